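"""Three-stage rule-based identification of US physician accounts.

Stage 1 keeps tweets that are in English and from the United States. Stage 2
flags accounts whose display name carries a literal medical-degree credential
(",MD", ", MD", ",M.D.", ",D.O.") or whose bio mentions "physician" or a
medical specialty as a whole token sequence. Stage 3 removes known
false-positive patterns: recruiter accounts ("jobs" in handle or bio),
students ("aspiring"/"future" in bio), and — in a two-step tweet-text screen —
business accounts that tweeted #job/#jobs and carry "medical" or "surgery" in
the display name.

Credential patterns are matched case-sensitively ("Md"/"md" rarely denote the
degree); all other terms match case-insensitively. Matching is literal: the
default rule set is a reconstruction and is user-editable via
:meth:`RuleSet.from_file`.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, fields, replace
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .hashtags import extract_hashtags
from .records import NON_PHYSICIAN, PHYSICIAN, AccountProfile, TweetRecord
from .utils import contains_token_sequence

logger = logging.getLogger("medtweet.identify")


def load_specialty_corpus() -> tuple[str, ...]:
    """Packaged specialty/subspecialty word list (bio inclusion terms)."""
    ref = resources.files("medtweet.data").joinpath("specialties.txt")
    terms = []
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.append(line.lower())
    return tuple(terms)


_DEFAULT_CREDENTIALS = (",M.D.", ",MD", ", MD", ",D.O.")


@dataclass(frozen=True)
class RuleSet:
    """The classifier's configuration: inclusion and exclusion patterns."""

    name_credential_patterns: tuple[str, ...] = _DEFAULT_CREDENTIALS
    bio_inclusion_terms: tuple[str, ...] = ("physician",)
    specialty_corpus: tuple[str, ...] = field(
        default_factory=load_specialty_corpus
    )
    username_bio_exclusion_terms: tuple[str, ...] = ("jobs",)
    bio_exclusion_terms: tuple[str, ...] = ("aspiring", "future")
    text_stage_hashtags: tuple[str, ...] = ("#job", "#jobs")
    text_stage_name_terms: tuple[str, ...] = ("medical", "surgery")

    @property
    def all_bio_inclusion_terms(self) -> tuple[str, ...]:
        return tuple(self.bio_inclusion_terms) + tuple(self.specialty_corpus)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for f in fields(self):
                fh.write(f"[{f.name}]\n")
                for term in getattr(self, f.name):
                    fh.write(term + "\n")
                fh.write("\n")

    @classmethod
    def from_file(cls, path) -> "RuleSet":
        sections: dict[str, list[str]] = {}
        current: list[str] | None = None
        valid = {f.name for f in fields(cls)}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith("[") and line.endswith("]"):
                    name = line[1:-1]
                    if name not in valid:
                        raise ValueError(f"unknown rule section {name!r}")
                    current = sections.setdefault(name, [])
                elif current is not None:
                    current.append(line)
                else:
                    raise ValueError("rule term before any [section] header")
        return cls(**{k: tuple(v) for k, v in sections.items()})


@dataclass(frozen=True)
class ClassificationOutcome:
    """Per-account result with stage flags and the rules that fired."""

    account_id: str
    passed_geo: bool
    matched_inclusion: bool
    excluded_profile: bool
    excluded_text_stage: bool
    matched_rules: tuple[str, ...]
    final_label: str

    @staticmethod
    def compose_label(
        passed_geo: bool,
        matched_inclusion: bool,
        excluded_profile: bool,
        excluded_text_stage: bool,
    ) -> str:
        if (
            passed_geo
            and matched_inclusion
            and not excluded_profile
            and not excluded_text_stage
        ):
            return PHYSICIAN
        return NON_PHYSICIAN


def geo_language_filter(tweets: Sequence[TweetRecord]) -> list[TweetRecord]:
    """Keep tweets with language "en" and country "US", order preserved."""
    return [
        t
        for t in tweets
        if getattr(t, "language", None) == "en"
        and getattr(t, "country", None) == "US"
    ]


def match_inclusion(
    profile: AccountProfile, rules: RuleSet | None = None
) -> tuple[bool, list[str]]:
    """Stage-2 Boolean inclusion over display name and bio."""
    rules = rules or RuleSet()
    fired: list[str] = []
    for pat in rules.name_credential_patterns:
        if pat in profile.display_name:
            fired.append(f"name_credential:{pat}")
    for term in rules.bio_inclusion_terms:
        if contains_token_sequence(profile.bio, term):
            fired.append(f"bio_incl:{term}")
    for term in rules.specialty_corpus:
        if contains_token_sequence(profile.bio, term):
            fired.append(f"specialty:{term}")
    return bool(fired), fired


def apply_profile_exclusions(
    profile: AccountProfile, rules: RuleSet | None = None
) -> tuple[bool, list[str]]:
    """Stage-3 profile exclusions (recruiters, students)."""
    rules = rules or RuleSet()
    fired: list[str] = []
    handle_l = profile.handle.lower()
    bio_l = profile.bio.lower()
    for term in rules.username_bio_exclusion_terms:
        t = term.lower()
        if t in handle_l or t in bio_l:
            fired.append(f"handle_bio_excl:{term}")
    for term in rules.bio_exclusion_terms:
        if term.lower() in bio_l:
            fired.append(f"bio_excl:{term}")
    return bool(fired), fired


def text_stage_filter(
    tweets: Sequence[TweetRecord],
    profiles: Iterable[AccountProfile],
    rules: RuleSet | None = None,
) -> set[str]:
    """Two-step tweet-text screen for business/recruiter accounts.

    Step 1 finds accounts with at least one tweet whose hashtags include a
    ``text_stage_hashtag`` (exact match after lowercasing). Step 2 eliminates
    those whose display name contains a ``text_stage_name_term``.
    """
    rules = rules or RuleSet()
    wanted = {h.lower().lstrip("#") for h in rules.text_stage_hashtags}
    job_accounts: set[str] = set()
    for t in tweets:
        if t.account_id in job_accounts:
            continue
        if any(tag in wanted for tag in extract_hashtags(t.text)):
            job_accounts.add(t.account_id)
    logger.info(
        "text_stage step 1: %d account(s) tweeted %s",
        len(job_accounts),
        sorted(wanted),
    )
    by_id = {p.account_id: p for p in profiles}
    excluded = {
        aid
        for aid in job_accounts
        if aid in by_id
        and any(
            term.lower() in by_id[aid].display_name.lower()
            for term in rules.text_stage_name_terms
        )
    }
    logger.info(
        "text_stage step 2: %d account(s) eliminated by name terms",
        len(excluded),
    )
    return excluded


def classify_accounts(
    tweets: Sequence[TweetRecord],
    profiles: Iterable[AccountProfile],
    rules: RuleSet | None = None,
) -> list[ClassificationOutcome]:
    """Run the full 3-stage classification.

    Emits one outcome per account having at least one geo-passing tweet
    (accounts never seen tweeting in English from the US do not enter the
    funnel). Pure function of (tweets, profiles, rules); outcomes are sorted
    by account_id.
    """
    rules = rules or RuleSet()
    profiles = list(profiles)
    by_id = {p.account_id: p for p in profiles}
    geo = geo_language_filter(tweets)
    candidates = sorted({t.account_id for t in geo})
    missing = [aid for aid in candidates if aid not in by_id]
    if missing:
        from .errors import CorpusIntegrityError

        raise CorpusIntegrityError(missing[0])
    text_excluded = text_stage_filter(geo, profiles, rules)
    outcomes = []
    for aid in candidates:
        profile = by_id[aid]
        matched, fired_in = match_inclusion(profile, rules)
        excluded, fired_ex = apply_profile_exclusions(profile, rules)
        excl_text = aid in text_excluded
        outcomes.append(
            ClassificationOutcome(
                account_id=aid,
                passed_geo=True,
                matched_inclusion=matched,
                excluded_profile=excluded,
                excluded_text_stage=excl_text,
                matched_rules=tuple(fired_in + fired_ex),
                final_label=ClassificationOutcome.compose_label(
                    True, matched, excluded, excl_text
                ),
            )
        )
    n_phys = sum(o.final_label == PHYSICIAN for o in outcomes)
    logger.info(
        "classify: %d tweets -> %d geo tweets -> %d candidate accounts -> "
        "%d physician accounts",
        len(tweets),
        len(geo),
        len(candidates),
        n_phys,
    )
    return outcomes


def outcomes_to_frame(outcomes: Sequence[ClassificationOutcome]) -> pd.DataFrame:
    cols = [
        "account_id",
        "passed_geo",
        "matched_inclusion",
        "excluded_profile",
        "excluded_text_stage",
        "matched_rules",
        "final_label",
    ]
    return pd.DataFrame(
        [
            (
                o.account_id,
                o.passed_geo,
                o.matched_inclusion,
                o.excluded_profile,
                o.excluded_text_stage,
                ";".join(o.matched_rules),
                o.final_label,
            )
            for o in outcomes
        ],
        columns=cols,
    )


_REQUIRED_COLUMNS = (
    "account_id",
    "handle",
    "display_name",
    "bio",
    "text",
    "language",
    "country",
)


class PhysicianTweetClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn wrapper over the 3-stage rule classifier.

    ``X`` is a tweet-level DataFrame (one row per tweet with the authoring
    account's fields denormalized onto it: ``account_id``, ``handle``,
    ``display_name``, ``bio``, ``text``, ``language``, ``country``, and
    optionally ``verified``/``timestamp``). There is nothing to learn —
    ``fit`` validates the input schema and freezes the rule set — but the
    estimator contract makes the classifier composable with sklearn
    pipelines and model selection.

    ``predict`` returns one label per tweet row (the label of its account).
    """

    def __init__(self, ruleset: RuleSet | None = None):
        self.ruleset = ruleset

    def fit(self, X: pd.DataFrame, y=None) -> "PhysicianTweetClassifier":
        self._validate_frame(X)
        self.ruleset_ = self.ruleset if self.ruleset is not None else RuleSet()
        self.classes_ = np.array([NON_PHYSICIAN, PHYSICIAN])
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "ruleset_")
        self._validate_frame(X)
        outcomes = self.classify(X)
        label_of = dict(zip(outcomes["account_id"], outcomes["final_label"]))
        return np.array(
            [label_of.get(aid, NON_PHYSICIAN) for aid in X["account_id"]],
            dtype=object,
        )

    def classify(self, X: pd.DataFrame) -> pd.DataFrame:
        """Account-level outcomes frame for a tweet-level input frame."""
        check_is_fitted(self, "ruleset_")
        accounts, tweets = _frame_to_corpus(X)
        return outcomes_to_frame(
            classify_accounts(tweets, accounts, self.ruleset_)
        )

    @staticmethod
    def _validate_frame(X) -> None:
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "X must be a tweet-level pandas DataFrame; got "
                f"{type(X).__name__}"
            )
        missing = [c for c in _REQUIRED_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"X is missing required columns: {missing}")


def _frame_to_corpus(
    X: pd.DataFrame,
) -> tuple[list[AccountProfile], list[TweetRecord]]:
    from datetime import datetime, timezone

    accounts: dict[str, AccountProfile] = {}
    tweets: list[TweetRecord] = []
    fallback_ts = datetime(1970, 1, 1, tzinfo=timezone.utc)
    for i, row in enumerate(X.itertuples(index=False)):
        aid = str(row.account_id)
        if aid not in accounts:
            accounts[aid] = AccountProfile(
                account_id=aid,
                handle=str(row.handle),
                display_name=str(row.display_name),
                bio=str(row.bio),
                verified=bool(getattr(row, "verified", False)),
                country=str(row.country),
            )
        ts = getattr(row, "timestamp", fallback_ts)
        if isinstance(ts, str):
            ts = datetime.fromisoformat(ts)
        if isinstance(ts, pd.Timestamp):
            ts = ts.to_pydatetime()
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        tweets.append(
            TweetRecord(
                tweet_id=str(getattr(row, "tweet_id", i)),
                account_id=aid,
                text=str(row.text),
                timestamp=ts,
                language=str(row.language),
                country=str(row.country),
                verified=bool(getattr(row, "verified", False)),
            )
        )
    return list(accounts.values()), tweets
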