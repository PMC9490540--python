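"""Corpus readers/writers, pipeline configuration, and the pipeline driver.

Record streams are line-delimited JSON (one object per line, UTF-8) with the
field names of :class:`~medtweet.records.AccountProfile` and
:class:`~medtweet.records.TweetRecord`; all report tables are tab-separated
text with headers. Per-stage record counts are logged so the identification
funnel can be reconstructed from the log alone.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .activity import activity_table, yearly_activity
from .errors import (
    ConfigurationError,
    CorpusIntegrityError,
    CorpusParseError,
    PipelineStageError,
)
from .hashtags import ThemeMap, assign_themes, tally_by_year, word_frequencies
from .identify import RuleSet, classify_accounts, outcomes_to_frame
from .records import PHYSICIAN, AccountProfile, TweetRecord
from .validate import validate_outcomes

logger = logging.getLogger("medtweet.io")

ACCOUNTS_FILENAME = "accounts.jsonl"
TWEETS_FILENAME = "tweets.jsonl"

_ACCOUNT_REQUIRED = {
    "account_id", "handle", "display_name", "bio", "verified", "country",
}
_TWEET_REQUIRED = {
    "tweet_id", "account_id", "text", "timestamp", "language", "country",
    "verified",
}


class Corpus(NamedTuple):
    accounts: list[AccountProfile]
    tweets: list[TweetRecord]
    n_malformed: int


def write_corpus(
    accounts: Iterable[AccountProfile],
    tweets: Iterable[TweetRecord],
    out_dir,
) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    apath, tpath = out / ACCOUNTS_FILENAME, out / TWEETS_FILENAME
    with open(apath, "w", encoding="utf-8") as fh:
        for a in accounts:
            fh.write(json.dumps(a.to_json_dict(), sort_keys=True) + "\n")
    with open(tpath, "w", encoding="utf-8") as fh:
        for t in tweets:
            fh.write(json.dumps(t.to_json_dict(), sort_keys=True) + "\n")
    return apath, tpath


def _read_jsonl(path, required, factory, strict):
    records = []
    malformed = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                missing = required - obj.keys()
                if missing:
                    raise ValueError(f"missing fields {sorted(missing)}")
                records.append(factory(obj))
            except (ValueError, TypeError, KeyError) as exc:
                if strict:
                    raise CorpusParseError(lineno, str(exc)) from exc
                malformed.append(lineno)
    if malformed:
        logger.warning(
            "%s: %d malformed line(s) skipped (lines %s%s)",
            path, len(malformed), malformed[:10],
            "..." if len(malformed) > 10 else "",
        )
    return records, len(malformed)


def read_corpus(path, tweets_path=None, *, strict: bool = False) -> Corpus:
    """Read a corpus from a directory or an explicit pair of JSONL files.

    Malformed lines are counted, logged, and skipped (``strict=True`` raises
    :class:`CorpusParseError` with the line number instead). A tweet whose
    ``account_id`` does not resolve raises :class:`CorpusIntegrityError`.
    """
    if tweets_path is None:
        base = Path(path)
        apath, tpath = base / ACCOUNTS_FILENAME, base / TWEETS_FILENAME
    else:
        apath, tpath = Path(path), Path(tweets_path)
    accounts, bad_a = _read_jsonl(
        apath, _ACCOUNT_REQUIRED, AccountProfile.from_json_dict, strict
    )
    tweets, bad_t = _read_jsonl(
        tpath, _TWEET_REQUIRED, TweetRecord.from_json_dict, strict
    )
    known = {a.account_id for a in accounts}
    for t in tweets:
        if t.account_id not in known:
            raise CorpusIntegrityError(t.account_id)
    return Corpus(accounts, tweets, bad_a + bad_t)


def corpus_to_frame(
    accounts: Iterable[AccountProfile], tweets: Iterable[TweetRecord]
) -> pd.DataFrame:
    """Denormalized tweet-level DataFrame (account fields joined onto tweets)."""
    by_id = {a.account_id: a for a in accounts}
    rows = []
    for t in tweets:
        a = by_id[t.account_id]
        rows.append(
            {
                "tweet_id": t.tweet_id,
                "account_id": t.account_id,
                "handle": a.handle,
                "display_name": a.display_name,
                "bio": a.bio,
                "text": t.text,
                "timestamp": t.timestamp.isoformat(),
                "language": t.language,
                "country": t.country,
                "verified": t.verified,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tweet_id", "account_id", "handle", "display_name", "bio",
            "text", "timestamp", "language", "country", "verified",
        ],
    )


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_labels(path) -> dict[str, bool]:
    """Delimited label table with columns (account_id, is_physician)."""
    df = pd.read_csv(path, sep="\t", dtype={"account_id": str})
    truthy = {"true", "1", "yes", "physician"}
    return {
        str(r.account_id): str(r.is_physician).strip().lower() in truthy
        for r in df.itertuples(index=False)
    }


def write_labels(labels: Mapping[str, bool], path) -> Path:
    df = pd.DataFrame(
        sorted(labels.items()), columns=["account_id", "is_physician"]
    )
    return write_table(df, path)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    input_dir: str | Path
    out_dir: str | Path
    rules_path: str | Path | None = None
    years: tuple[int, int] = (2016, 2020)
    sample_fraction: float = 0.05
    confidence_level: float = 0.95
    top_k: int = 100
    top_k_only: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ConfigurationError("sample_fraction", "must be in (0, 1]")
        if not 0.0 < self.confidence_level < 1.0:
            raise ConfigurationError("confidence_level", "must be in (0, 1)")
        if self.top_k < 1:
            raise ConfigurationError("top_k", "must be >= 1")
        if self.years[1] < self.years[0]:
            raise ConfigurationError("years", "range must be non-empty")


def parse_config_file(path) -> dict[str, str]:
    """Flat ``key = value`` text config; '#' comments and blank lines ignored."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if "=" not in stripped:
                raise CorpusParseError(lineno, f"expected key = value: {stripped!r}")
            key, _, value = stripped.partition("=")
            out[key.strip()] = value.strip()
    return out


def config_from_mapping(m: Mapping[str, str]) -> PipelineConfig:
    kwargs: dict = {"input_dir": m["input_dir"], "out_dir": m["out_dir"]}
    if "rules_path" in m:
        kwargs["rules_path"] = m["rules_path"]
    if "years" in m:
        y0, _, y1 = m["years"].partition(":")
        kwargs["years"] = (int(y0), int(y1 or y0))
    for key, cast in (
        ("sample_fraction", float),
        ("confidence_level", float),
        ("top_k", int),
        ("seed", int),
    ):
        if key in m:
            kwargs[key] = cast(m[key])
    if "top_k_only" in m:
        kwargs["top_k_only"] = m["top_k_only"].strip().lower() in {
            "1", "true", "yes",
        }
    return PipelineConfig(**kwargs)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineStageError(name, exc) from exc

    return wrap


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """classify -> validate (if labels present) -> activity -> hashtags.

    Writes every report table under ``config.out_dir`` and returns the
    bundle as DataFrames. Per-stage in/out counts are logged on the
    ``medtweet.io`` logger (the identification funnel).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rules = (
        RuleSet.from_file(config.rules_path) if config.rules_path else RuleSet()
    )

    try:
        accounts, tweets, n_malformed = read_corpus(config.input_dir)
    except Exception as exc:
        raise PipelineStageError("read", exc) from exc
    logger.info(
        "stage read: %d accounts, %d tweets in (%d malformed skipped)",
        len(accounts), len(tweets), n_malformed,
    )

    outcomes = _stage("classify")(classify_accounts, tweets, accounts, rules)
    outcomes_df = outcomes_to_frame(outcomes)
    physician_ids = {
        o.account_id for o in outcomes if o.final_label == PHYSICIAN
    }
    funnel = pd.DataFrame(
        [
            ("tweets_in", len(tweets)),
            ("tweets_geo_passed", sum(
                1 for t in tweets if t.language == "en" and t.country == "US"
            )),
            ("accounts_candidate", len(outcomes)),
            ("accounts_matched_inclusion", sum(
                1 for o in outcomes if o.matched_inclusion
            )),
            ("accounts_after_profile_exclusions", sum(
                1 for o in outcomes
                if o.matched_inclusion and not o.excluded_profile
            )),
            ("accounts_physician", len(physician_ids)),
        ],
        columns=["stage", "count"],
    )
    for row in funnel.itertuples(index=False):
        logger.info("funnel %s: %d", row.stage, row.count)

    bundle: dict[str, pd.DataFrame] = {
        "outcomes": outcomes_df,
        "funnel": funnel,
    }

    labels = {
        a.account_id: a.true_label == PHYSICIAN
        for a in accounts
        if a.true_label is not None
    }
    if labels and physician_ids <= labels.keys():
        verified_ids = {a.account_id for a in accounts if a.verified}
        results = _stage("validate")(
            validate_outcomes,
            physician_ids,
            verified_ids,
            labels,
            fraction=config.sample_fraction,
            seed=config.seed,
            level=config.confidence_level,
        )
        bundle["validation"] = pd.DataFrame([vars(r) for r in results])
    else:
        bundle["validation"] = pd.DataFrame(
            columns=[
                "stratum", "n_reviewed", "n_false_positive",
                "accuracy_percent", "ci_low_percent", "ci_high_percent",
                "confidence_level",
            ]
        )

    activity = _stage("activity")(
        yearly_activity, tweets, physician_ids, config.years
    )
    bundle["activity"] = activity
    bundle["activity_table"] = activity_table(activity)

    phys_tweets = [t for t in tweets if t.account_id in physician_ids]
    bundle["tallies"] = _stage("hashtags")(
        tally_by_year, phys_tweets, config.top_k
    )
    full_tallies = tally_by_year(phys_tweets, None)
    bundle["themes"] = assign_themes(
        full_tallies,
        ThemeMap.default(),
        top_k=config.top_k,
        top_k_only=config.top_k_only,
    )
    bundle["wordfreq"] = word_frequencies(phys_tweets)

    write_table(outcomes_df, out_dir / "outcomes.tsv")
    write_table(funnel, out_dir / "funnel.tsv")
    write_table(bundle["validation"], out_dir / "validation.tsv")
    write_table(activity, out_dir / "activity.tsv")
    write_table(bundle["activity_table"], out_dir / "activity_table.tsv")
    write_table(bundle["themes"], out_dir / "themes_by_year.tsv")
    tallies = bundle["tallies"]
    years_with_tags = (
        sorted(tallies["year"].unique()) if not tallies.empty else []
    )
    for year in years_with_tags:
        write_table(
            tallies[tallies["year"] == year],
            out_dir / f"hashtag_tallies_{year}.tsv",
        )
    wf = bundle["wordfreq"]
    for year in sorted(wf["year"].unique()) if not wf.empty else []:
        write_table(wf[wf["year"] == year], out_dir / f"wordfreq_{year}.tsv")
    return bundle
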