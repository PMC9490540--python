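"""Seeded synthetic tweet corpora with known ground-truth physician labels.

No public tweet archive exists for this problem (the study data came from a
proprietary firehose vendor), so every downstream stage is exercised on
generated corpora that emulate the documented population structure:

* physician accounts signalling status through a comma-credential in the
  display name (",MD", ", MD", ",M.D.", ",D.O.") or through "physician" /
  a specialty term in the bio;
* trap accounts engineered to trigger known false-positive patterns —
  "MD" meaning Maryland, physician-recruiter accounts with "jobs" in the
  handle or bio, "aspiring"/"future physician" students, plain
  "@Doctor..." handles, and business accounts named "... Medical" /
  "... Surgery" that tweet #jobs;
* per-year hashtag usage drawn from theme-specific weights (COVID-19 and
  social-activism tags concentrated in 2020, politics in election years);
* a configurable fraction of non-US or non-English tweets.

Maryland-credential traps survive every filter by construction: they are the
residual false-positive mode, so the generator's default mixture yields a
classifier precision near 0.30/(0.30+0.03) ~= 91%.

Everything is deterministic given ``GeneratorConfig.seed``.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np

from .errors import ConfigurationError
from .hashtags import ThemeMap
from .records import NON_PHYSICIAN, PHYSICIAN, AccountProfile, TweetRecord

TRAP_KINDS = (
    "maryland_md",
    "recruiter_jobs",
    "aspiring_student",
    "doctor_handle_only",
    "medical_business",
)

DEFAULT_TRAP_FRACTIONS: Mapping[str, float] = {
    "maryland_md": 0.03,
    "recruiter_jobs": 0.04,
    "aspiring_student": 0.04,
    "doctor_handle_only": 0.04,
    "medical_business": 0.03,
}

OTHER_THEME = "other"

# Hashtags with no theme, emulating the long tail of a real corpus.
OTHER_HASHTAGS = (
    "coffee", "travel", "weekend", "sports", "news", "photo",
    "music", "food", "life", "fun", "books", "running",
)

_BASE_WEIGHTS: Mapping[str, float] = {
    "general health care": 0.05,
    "covid19 and public health": 0.0,
    "politics": 0.03,
    "social activism": 0.001,
    "mental health and well-being": 0.03,
    "health technology": 0.025,
    "conferences": 0.015,
    "patient groups": 0.01,
    "specialties and subspecialties": 0.025,
    "medical conditions and procedures": 0.02,
    "medical education": 0.02,
}


def _year_weights(**overrides: float) -> dict[str, float]:
    w = dict(_BASE_WEIGHTS)
    w.update(overrides)
    w[OTHER_THEME] = max(0.0, 1.0 - sum(w.values()))
    return w


# Per-year theme weights echoing the corpus the pipeline is built to study:
# election-year politics bumps (2016, 2020); COVID-19 at ~10.6% and social
# activism at ~0.3% of 2020 hashtag occurrences; general health care ~5%.
DEFAULT_THEME_WEIGHTS: Mapping[int, Mapping[str, float]] = {
    2016: _year_weights(politics=0.05, **{"health technology": 0.035}),
    2017: _year_weights(politics=0.03),
    2018: _year_weights(politics=0.04, **{"social activism": 0.004}),
    2019: _year_weights(politics=0.04, **{"social activism": 0.004}),
    2020: _year_weights(
        politics=0.05,
        **{
            "covid19 and public health": 0.106,
            "social activism": 0.003,
            "medical education": 0.007,
            "specialties and subspecialties": 0.023,
        },
    ),
}

_FIRST_NAMES = (
    "Jane", "John", "Maria", "Wei", "Aisha", "Carlos", "Emily", "Raj",
    "Sofia", "Ahmed", "Grace", "Liam", "Noor", "Diego", "Hana", "Ivan",
    "Keisha", "Mateo", "Priya", "Tomás", "Yuki", "Omar", "Lena", "Sam",
)

_LAST_NAMES = (
    "Doe", "Smith", "Garcia", "Chen", "Patel", "Okafor", "Kim", "Nguyen",
    "Hernandez", "Brown", "Silva", "Khan", "Ivanov", "Rossi", "Sato",
    "Jones", "Miller", "Ali", "Novak", "Costa", "Haddad", "Park",
)

_CITIES = (
    "Austin", "Boston", "Chicago", "Dallas", "Denver", "Miami",
    "Phoenix", "Portland", "Seattle", "Tampa",
)

_PHYS_BIO_NEUTRAL = (
    "Parent. Runner. Views my own.",
    "Tweets are not medical advice.",
    "Science nerd. Coffee first.",
    "Opinions mine, RT != endorsement.",
)

_PHYS_BIO_SIGNAL = (
    "{Specialty} physician at {city} General.",
    "Academic {specialty}. Educator and researcher.",
    "Board-certified {specialty}. Physician advocate.",
    "Attending physician, {specialty} service.",
)

_ORDINARY_BIOS = (
    "Coffee, code, and cats.",
    "Proud parent. Hot takes only.",
    "Travel photos and bad puns.",
    "Weekend hiker. Amateur cook.",
    "Here for the memes.",
)

_MARYLAND_BIOS = (
    "Realtor serving families across MD.",
    "Student living in MD, Orioles fan.",
    "Annapolis MD | small-business owner.",
)

_ASPIRING_BIOS = (
    "Aspiring Infectious Disease Physician",
    "aspiring physician working in epi & vaccine research",
    "Future physician. Premed and proud.",
    "MS2. future physician, coffee-dependent.",
)

_TWEET_PHRASES = (
    "Long day on the wards.",
    "Interesting read today.",
    "Grateful for my team.",
    "Big news this morning.",
    "What a week.",
    "Thread:",
    "Thoughts?",
    "Sharing this again.",
)

_NON_US_COUNTRIES = ("GB", "CA", "IN", "AU", "BR")
_NON_EN_LANGUAGES = ("es", "fr", "de", "pt")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic corpus.

    Defaults are the conditions the pipeline is validated under: a 5-year
    window (2016-2020), a 30% physician prevalence among candidate accounts,
    trap kinds at 3-4% each, Poisson tweet counts, and per-year theme
    weights concentrating COVID-19 and activism hashtags in 2020.
    """

    n_accounts: int = 2000
    physician_fraction: float = 0.30
    trap_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAP_FRACTIONS)
    )
    years: tuple[int, int] = (2016, 2020)
    tweets_per_account_mean: float = 8.0  # per year
    theme_hashtag_weights: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: {
            y: dict(w) for y, w in DEFAULT_THEME_WEIGHTS.items()
        }
    )
    hashtags_per_tweet_mean: float = 0.8
    non_us_fraction: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_accounts < 0:
            raise ConfigurationError("n_accounts", "must be >= 0")
        if not 0.0 <= self.physician_fraction <= 1.0:
            raise ConfigurationError("physician_fraction", "must be in [0, 1]")
        for kind, frac in self.trap_fractions.items():
            if kind not in TRAP_KINDS:
                raise ConfigurationError(
                    "trap_fractions", f"unknown trap kind {kind!r}"
                )
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(
                    "trap_fractions", f"{kind} fraction must be in [0, 1]"
                )
        total = self.physician_fraction + sum(self.trap_fractions.values())
        if total > 1.0 + 1e-12:
            raise ConfigurationError(
                "trap_fractions",
                f"physician_fraction + trap fractions = {total:.3f} > 1",
            )
        y0, y1 = self.years
        if y1 < y0:
            raise ConfigurationError("years", "range must be non-empty")
        if self.tweets_per_account_mean <= 0:
            raise ConfigurationError("tweets_per_account_mean", "must be > 0")
        if self.hashtags_per_tweet_mean < 0:
            raise ConfigurationError("hashtags_per_tweet_mean", "must be >= 0")
        if not 0.0 <= self.non_us_fraction <= 1.0:
            raise ConfigurationError("non_us_fraction", "must be in [0, 1]")
        for year, weights in self.theme_hashtag_weights.items():
            for theme, w in weights.items():
                if w < 0:
                    raise ConfigurationError(
                        "theme_hashtag_weights",
                        f"negative weight for {theme!r} in {year}",
                    )


def _pick(rng: np.random.Generator, seq):
    return seq[int(rng.integers(0, len(seq)))]


def _make_physician(i, rng, first, last, city, specialty) -> AccountProfile:
    if rng.random() < 0.7:
        cred = _pick(rng, (", MD", ",MD", ",M.D.", ",D.O."))
        display = f"{first} {last}{cred}"
        bio = _pick(rng, _PHYS_BIO_NEUTRAL + _PHYS_BIO_SIGNAL[:1]).format(
            Specialty=specialty.capitalize(), specialty=specialty, city=city
        )
    else:
        display = f"{first} {last}"
        bio = _pick(rng, _PHYS_BIO_SIGNAL).format(
            Specialty=specialty.capitalize(), specialty=specialty, city=city
        )
    return AccountProfile(
        account_id=f"A{i:06d}",
        handle=f"@{first.lower()}{last.lower()}_{i:05d}",
        display_name=display,
        bio=bio,
        verified=bool(rng.random() < 0.02),
        country="US",
        true_label=PHYSICIAN,
        synthetic_kind="physician",
    )


def _make_trap(kind, i, rng, first, last, city, specialty) -> AccountProfile:
    handle = f"@{first.lower()}{last.lower()}_{i:05d}"
    if kind == "maryland_md":
        display = f"{first} {last}, MD"  # MD = Maryland
        bio = _pick(rng, _MARYLAND_BIOS)
    elif kind == "recruiter_jobs":
        if rng.random() < 0.5:
            display = f"{first} {last}, MD Recruiter"
            handle = f"@{last.lower()}MDjobs_{i:05d}"
            bio = "Connecting clinicians with top hospital openings."
        else:
            display = f"{city} Physician Staffing"
            bio = "Physician jobs posted daily. DM to apply."
    elif kind == "aspiring_student":
        display = f"{first} {last}"
        bio = _pick(rng, _ASPIRING_BIOS)
    elif kind == "doctor_handle_only":
        display = f"Doctor {last}"
        handle = f"@Doctor{last}_{i:05d}"
        bio = "Here to help. Opinions my own."
    elif kind == "medical_business":
        display = _pick(
            rng,
            (
                f"{last} Medical",
                f"{city} Facial Plastic Surgery",
                f"{last} Surgery Center",
                f"{city} Medical Group",
            ),
        )
        bio = f"Now hiring! {specialty.capitalize()} clinic in {city}."
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(kind)
    return AccountProfile(
        account_id=f"A{i:06d}",
        handle=handle,
        display_name=display,
        bio=bio,
        verified=bool(rng.random() < 0.002),
        country="US",
        true_label=NON_PHYSICIAN,
        synthetic_kind=kind,
    )


def _make_ordinary(i, rng, first, last) -> AccountProfile:
    return AccountProfile(
        account_id=f"A{i:06d}",
        handle=f"@{first.lower()}{last.lower()}_{i:05d}",
        display_name=f"{first} {last}",
        bio=_pick(rng, _ORDINARY_BIOS),
        verified=bool(rng.random() < 0.002),
        country="US" if rng.random() < 0.85 else _pick(rng, _NON_US_COUNTRIES),
        true_label=NON_PHYSICIAN,
        synthetic_kind="ordinary",
    )


def generate_accounts(config: GeneratorConfig) -> list[AccountProfile]:
    """Generate ``config.n_accounts`` profiles with ground-truth labels."""
    config.validate()
    from .identify import load_specialty_corpus

    specialties = load_specialty_corpus()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n = config.n_accounts
    kinds = ["physician"] * int(round(config.physician_fraction * n))
    for kind in TRAP_KINDS:
        k = int(round(config.trap_fractions.get(kind, 0.0) * n))
        kinds.extend([kind] * k)
    kinds = kinds[:n]
    kinds.extend(["ordinary"] * (n - len(kinds)))
    order = rng.permutation(n)
    kinds = [kinds[j] for j in order]

    profiles = []
    for i, kind in enumerate(kinds):
        first = _pick(rng, _FIRST_NAMES)
        last = _pick(rng, _LAST_NAMES)
        city = _pick(rng, _CITIES)
        specialty = _pick(rng, specialties)
        if kind == "physician":
            profiles.append(_make_physician(i, rng, first, last, city, specialty))
        elif kind == "ordinary":
            profiles.append(_make_ordinary(i, rng, first, last))
        else:
            profiles.append(_make_trap(kind, i, rng, first, last, city, specialty))
    return profiles


def _theme_pools(theme_map: ThemeMap) -> dict[str, tuple[str, ...]]:
    pools = {t: tuple(sorted(tags)) for t, tags in theme_map.themes.items()}
    pools[OTHER_THEME] = OTHER_HASHTAGS
    return pools


def _sample_hashtags(rng, year, config, pools) -> list[str]:
    k = int(rng.poisson(config.hashtags_per_tweet_mean))
    if k == 0:
        return []
    weights = config.theme_hashtag_weights.get(year) or {OTHER_THEME: 1.0}
    themes = sorted(t for t in weights if weights[t] > 0 and t in pools)
    if not themes:
        return []
    p = np.array([weights[t] for t in themes], dtype=float)
    p /= p.sum()
    tags = []
    for idx in rng.choice(len(themes), size=k, p=p):
        tags.append("#" + _pick(rng, pools[themes[int(idx)]]))
    return tags


def generate_tweets(
    accounts, config: GeneratorConfig, theme_map: ThemeMap | None = None
) -> list[TweetRecord]:
    """Generate Poisson-count tweets per account per year.

    Hashtags are sampled from the year's theme weights; a ``non_us_fraction``
    of tweets carry a non-US country and/or a non-English language;
    ``medical_business`` traps additionally post one guaranteed "#jobs"
    tweet per year (the pattern the text stage exists to catch). Timestamps
    are uniform within each calendar year, UTC.
    """
    config.validate()
    theme_map = theme_map or ThemeMap.default()
    pools = _theme_pools(theme_map)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    y0, y1 = config.years
    tweets: list[TweetRecord] = []
    tid = 0
    for acct in sorted(accounts, key=lambda a: a.account_id):
        for year in range(y0, y1 + 1):
            n = int(rng.poisson(config.tweets_per_account_mean))
            forced_jobs = acct.synthetic_kind == "medical_business"
            for j in range(n + (1 if forced_jobs else 0)):
                start = datetime(year, 1, 1, tzinfo=timezone.utc)
                n_seconds = int(
                    (datetime(year + 1, 1, 1, tzinfo=timezone.utc) - start)
                    .total_seconds()
                )
                ts = start + timedelta(seconds=int(rng.integers(0, n_seconds)))
                if forced_jobs and j == 0:
                    text = f"#jobs opening — apply today at {acct.display_name}"
                    country, language = "US", "en"
                else:
                    text = _pick(rng, _TWEET_PHRASES)
                    tags = _sample_hashtags(rng, year, config, pools)
                    if tags:
                        text = text + " " + " ".join(tags)
                    country, language = "US", "en"
                    if rng.random() < config.non_us_fraction:
                        mode = int(rng.integers(0, 3))
                        if mode in (0, 2):
                            country = _pick(rng, _NON_US_COUNTRIES)
                        if mode in (1, 2):
                            language = _pick(rng, _NON_EN_LANGUAGES)
                tweets.append(
                    TweetRecord(
                        tweet_id=f"T{tid:08d}",
                        account_id=acct.account_id,
                        text=text,
                        timestamp=ts,
                        language=language,
                        country=country,
                        verified=acct.verified,
                    )
                )
                tid += 1
    return tweets


def generate_corpus(
    config: GeneratorConfig, theme_map: ThemeMap | None = None
) -> tuple[list[AccountProfile], list[TweetRecord]]:
    """Accounts and tweets in one call; deterministic given ``config.seed``."""
    accounts = generate_accounts(config)
    return accounts, generate_tweets(accounts, config, theme_map)
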