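# Methods

## Classification model

An account is labelled *physician* iff it authored at least one English-language
US tweet, matched the Boolean inclusion logic, and survived both exclusion
screens:

    physician ⇔ passed_geo ∧ matched_inclusion ∧ ¬excluded_profile ∧ ¬excluded_text_stage

The stages are pure functions of `(tweets, profiles, rules)`; the whole
pipeline is deterministic and order-independent at the account level.
Accounts with no geo-passing tweet never enter the funnel (the mining is
tweet-first: accounts are only observed through their tweets).

Matching semantics, where the method description is silent, were fixed as
follows and are encoded in the default `RuleSet` (every list is
user-editable via a plain-text rules file):

- **Credential patterns** (`,M.D.`, `,MD`, `, MD`, `,D.O.`) match
  case-sensitively, anywhere in the display name. "Md"/"md" rarely denote
  the degree, and the canonical false-positive examples ("MD Zeki",
  "@MDJobs") are capitalized. Matching is literal: "Jane Doe, M.D." (space
  before "M.D.") is *not* matched by the default list — add `, M.D.` to the
  rules file if your corpus uses that style.
- **Bio inclusion terms** ("physician" plus a packaged ~40-entry specialty
  corpus) match case-insensitively on whole token sequences, so
  "physicianship" does not fire and "plastic surgery fellow" does.
- **Exclusion terms** ("jobs" in handle or bio; "aspiring"/"future" in bio)
  match as lowercase substrings — "future physician" and "Future Physician
  Assistant" are both caught.
- **Text-stage hashtags** (`#job`, `#jobs`) match *exactly* after
  lowercasing (`#jobsearch` does not fire); "account name" means the display
  name, per the canonical examples ("Goldfish Medical"). The two steps —
  find job-hashtag tweeters, then filter by name term — are logged
  separately so the screen's funnel is observable.
- Rule identifiers are stable strings (`name_credential:, MD`,
  `bio_excl:aspiring`, …) recorded per account for auditability.

The iterative human-in-the-loop refinement is supported as an audit harness
(`audit_loop`): batches of 1000 classified tweets are scored against an
external label file and the per-batch false-positive rate is reported
against a strict 5% threshold. The harness never edits rules; rule revision
is a human decision.

## Validation statistics

Precision ("accuracy": the fraction of flagged accounts that are truly
physicians) is estimated by simple random sampling without replacement of
`round(f·N)` flagged accounts (default f = 0.05), deterministic given a
seed. Verified accounts form a separate stratum audited in full. The
confidence interval is the Wald normal approximation

    p̂ ± z_{(1+level)/2} · sqrt(p̂(1−p̂)/n)

clamped to [0, 100] and reported in percent with one-decimal
half-away-from-zero rounding (the convention used for every reported
percentage in the package). Wald is the default because it reproduces the
reference interval for 1774/1978 exactly (88.3–91.0); Wilson and
Clopper–Pearson are available via `method=` since Wald undercovers for
small n or extreme p̂. By binomial enumeration, exact Wald coverage at
n = 500, p = 0.9 is 94.3%, which is why the coverage test band is 93–97%.

Recall/sensitivity is not estimated on real data (accounts that never signal
their status are invisible to any rule set); on synthetic corpora the
generator's labels make it computable and the suite checks it.

## Activity metrics

Per calendar year (UTC boundaries) and stratum (`all`, `verified`): tweet
count, unique accounts tweeting, new accounts, and mean tweets per account
(one decimal). "New" is defined as first appearance *within the analysis
window*, since tweet exports carry no account-creation date; a `lookback`
set of previously seen account ids prevents the window's first year from
labelling every account new. Consequences of the definition:
Σ_year new = distinct accounts in window, and verified-stratum cells are
dominated by all-stratum cells. Percent change is
`100·(final−baseline)/baseline`, sign-preserving.

## Hashtag and theme analysis

A hashtag is a maximal run of word characters (Unicode letters, digits,
underscore) immediately after `#`, lowercased; `#` before punctuation emits
nothing. Tallies are per year over all occurrences; ranking is by descending
count with dense ranks and lexicographic tie-break, so the top-k list is a
prefix of the full ranking (deterministic under corpus shuffling).

Theme aggregation sums member-hashtag counts per year and reports them as a
percent of the year's **total hashtag occurrences** (the denominator is
never truncated). By default the numerator is restricted to the year's
top-100 hashtags (`top_k_only=True`), matching the convention of considering
only the top-100 list; both modes are exposed because the alternative
whole-corpus reading is defensible. The packaged default theme map carries
eleven themes with the explicitly documented member tags and is
user-extensible (`theme<TAB>hashtag` rows; a hashtag may belong to at most
one theme — overlaps are rejected at load, naming the duplicate).

The word-frequency export tokenizes tweets, lowercases, removes English stop
words (scikit-learn's built-in list), and applies an in-package
implementation of the classic Porter suffix-stripping stemmer to ordinary
words; hashtags pass through unstemmed. Stemming hashtags would corrupt the
tallies, so the two text paths are deliberately separate.

## Synthetic corpus generator

The generator defines the study conditions the suite validates under.
Defaults: 2,000 accounts over 2016–2020, physician prevalence 0.30 among
candidate accounts (the true prevalence is unknown; this is a free
parameter, not an estimate), trap kinds at 3–4% each, Poisson(8) tweets per
account per year, Poisson(0.8) hashtags per tweet, 25% of tweets non-US or
non-English, timestamps uniform within each year. Tweet counts are Poisson
because the reporting unit is "mean tweets per account" and a seedable
single-parameter count law suffices. These sizes are scaled down from the
population the method was designed for (tens of thousands of accounts,
millions of tweets); every metric tested is size-invariant or has its
sampling error accounted for at 3σ.

Trap kinds and their fate under the default rules:

| kind                 | construction                                | fate |
|----------------------|---------------------------------------------|------|
| `maryland_md`        | "First Last, MD" (Maryland), clean bio      | **false positive** (survives all filters) |
| `recruiter_jobs`     | ", MD Recruiter" name or "Physician jobs" bio, "jobs" in handle/bio | excluded at stage 3 |
| `aspiring_student`   | "aspiring/future physician" bio             | excluded at stage 3 |
| `doctor_handle_only` | "@DoctorX", no credential, no bio term      | never included |
| `medical_business`   | "… Medical"/"… Surgery" name, specialty bio, one forced `#jobs` tweet per year | excluded at text stage |

The Maryland-credential trap is deliberately unfixable by the rule set — it
is the residual false-positive mode the audit exists to quantify — so the
default mixture's structural precision is 0.30/(0.30+0.03) ≈ 90.9%, and
precision is exactly 100% when all trap fractions are zero. Per-year theme
weights default to election-year politics bumps and a 2020 concentration of
COVID-19 (10.6% of hashtag occurrences) and activism (0.3%) tags, with the
remaining mass on an unthemed long tail.

What the generator does **not** emulate: social-graph structure, retweets,
burstiness/seasonality within a year, bio drift over time, multilingual
code-switching, or adversarial self-description. Passing tests therefore
demonstrate correctness of the pipeline's mechanics and statistics under the
stated population model, not field performance on live platform data.

## Numerical conventions and edge cases

- All reported percentages and means: one decimal, half-away-from-zero
  (`decimal`-based, not banker's rounding).
- Audit sample size: `round(fraction · N)` half-away-from-zero, capped at N.
- Zero denominators raise `UndefinedInputError` for scalar helpers; the
  activity table reports an absent (NaN) mean for empty years instead of
  failing.
- Empty corpora flow through the whole pipeline and produce well-formed,
  empty (or zero-count) tables.
- Malformed corpus lines are counted and logged, never silently dropped;
  `strict=True` turns them into parse errors with line numbers. A tweet
  referencing an unknown account is always an integrity error.
- Seeds: the generator derives independent account/tweet streams from
  `(seed, 11)` and `(seed, 13)` seed sequences; identical configs are
  byte-identical on re-run.

## Known limitations

- The default rule set is a reconstruction from the documented rules and
  examples; the original full Boolean expression is not public, so the rules
  file is designed to be edited.
- Wald intervals degrade near p̂ = 0 or 1 and small n; use Wilson for small
  audits.
- The "new accounts" definition undercounts nothing but cannot distinguish
  a truly new account from one first observed in-window; supply `lookback`
  ids when prior data exists.
- A reported year-over-year growth figure for new accounts in the source
  material is not derivable from its printed counts under percent-change or
  CAGR definitions; no operation computes it.
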