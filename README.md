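# medtweet

Rule-based identification of US physician accounts in tweet corpora, with
audit-sampling validation, longitudinal activity metrics, and hashtag theme
analysis.

## The problem

Physicians self-identify on social media in varied and imprecise ways: a
credential in the display name ("Jane Doe, MD"), "physician" or a specialty
in the bio, or nothing at all. Naive pattern matching drowns in false
positives — "MD" meaning Maryland or Muhammad, recruiter accounts posting
physician *jobs*, "aspiring physician" students, and clinics named
"… Medical" or "… Surgery". `medtweet` implements a three-stage
identification pipeline for this population, plus the statistics used to
validate and characterize it:

1. **Geographic/language filter** — keep tweets in English from the US.
2. **Boolean inclusion** — flag accounts whose display name contains a
   literal medical-degree credential (`,MD`, `, MD`, `,M.D.`, `,D.O.`;
   case-sensitive) or whose bio mentions *physician* or a specialty name as
   a whole token sequence (case-insensitive).
3. **False-positive exclusions** — drop accounts with *jobs* in the handle
   or bio, or *aspiring*/*future* in the bio; then a two-step tweet-text
   screen eliminates accounts that tweeted `#job`/`#jobs` **and** carry
   *medical* or *surgery* in the display name.

Classifier precision is estimated by manual-review audit: a simple random
sample of a fraction *f* of flagged accounts is reviewed, and the accuracy
p̂ = (reviewed − false positives)/reviewed is reported with a Wald interval
p̂ ± z·√(p̂(1−p̂)/n) (Wilson and Clopper–Pearson available). Downstream
modules compute per-year activity (tweets, unique accounts, new accounts,
mean tweets/account, for all and verified-only strata), hashtag tallies with
top-k dense ranking, and theme aggregation (e.g. "covid19 and public
health") as shares of yearly hashtag occurrences.

Because real firehose data is proprietary, the package ships a seeded
synthetic-corpus generator (`medtweet.synthetic`) that emulates the
population structure above — including each documented false-positive trap —
with ground-truth labels, so every stage is testable end to end.

## Worked example

```sh
medtweet simulate --out demo/corpus --seed 42 --n-accounts 400
medtweet run --in demo/corpus --out demo/reports --seed 42
```

The funnel (`demo/reports/funnel.tsv`) shows the attrition at each stage:

```
                            stage  count
                        tweets_in  16003
                tweets_geo_passed  11992
               accounts_candidate    400
       accounts_matched_inclusion    176
accounts_after_profile_exclusions    144
               accounts_physician    132
```

400 candidate accounts shrink to 176 after Boolean inclusion, 144 after the
profile exclusions, and 132 after the tweet-text screen. The audit
(`validation.tsv`) reviews all verified flagged accounts and a 5% sample of
the unverified ones against the generator's ground truth:

```
   stratum  n_reviewed  n_false_positive  accuracy_percent  ci_low_percent  ci_high_percent
  verified           4                 0             100.0           100.0            100.0
unverified           6                 0             100.0           100.0            100.0
```

(At fraction 1.0 the audit recovers the exact precision — 90.9% on this
corpus, since the Maryland-credential traps survive every filter by design.)
`activity_table.tsv` gives the yearly metrics per stratum, and
`themes_by_year.tsv` the theme shares; in 2020 the corpus concentrates
COVID-19 hashtags, as configured:

```
 year                          theme  count  percent  denominator
 2020      covid19 and public health     94      9.9          949
 2020                       politics     49      5.2          949
```

The same operations are available as library functions
(`classify_accounts`, `audit_precision`, `yearly_activity`,
`tally_by_year`, `assign_themes`) and as a scikit-learn estimator,
`PhysicianTweetClassifier`, which takes a denormalized tweet-level
`DataFrame` and predicts a label per tweet row.

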