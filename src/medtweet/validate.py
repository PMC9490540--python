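"""Precision validation by audit sampling.

The classifier's precision (called "accuracy" in reporting: the fraction of
algorithm-positive accounts that are truly physicians) is estimated by manual
review of a simple random sample of flagged accounts. Verified accounts form
a separate, fully reviewed stratum; unverified accounts are sampled at a
configurable fraction (default 5%). Confidence intervals use the Wald
normal-approximation interval by default, with Wilson and Clopper-Pearson
available via ``method``.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .errors import MissingLabelError, UndefinedInputError
from .records import PHYSICIAN
from .utils import round_half_away

logger = logging.getLogger("medtweet.validate")


def sample_for_audit(
    account_ids: Iterable[str], fraction: float, seed: int
) -> set[str]:
    """Simple random sample without replacement of round(fraction * N) ids."""
    if not 0.0 < fraction <= 1.0:
        raise UndefinedInputError("fraction must be in (0, 1]")
    ids = sorted(set(account_ids))
    if not ids:
        logger.warning("sample_for_audit: empty account set")
        return set()
    size = int(round_half_away(fraction * len(ids), 0))
    size = min(size, len(ids))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=size, replace=False)
    return {ids[int(i)] for i in chosen}


def compute_accuracy(n_reviewed: int, n_false_positive: int) -> float:
    """Audit accuracy = 100 * (reviewed - FP) / reviewed, one decimal."""
    if n_reviewed <= 0:
        raise UndefinedInputError("n_reviewed must be > 0")
    if not 0 <= n_false_positive <= n_reviewed:
        raise UndefinedInputError("n_false_positive must be in [0, n_reviewed]")
    return round_half_away(
        100.0 * (n_reviewed - n_false_positive) / n_reviewed, 1
    )


def wald_interval(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Unrounded Wald interval on the proportion scale, clamped to [0, 1]."""
    if n <= 0 or not 0 <= successes <= n:
        raise UndefinedInputError("need 0 <= successes <= n and n > 0")
    if not 0.0 < level < 1.0:
        raise UndefinedInputError("level must be in (0, 1)")
    p = successes / n
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def proportion_ci(
    successes: int,
    n: int,
    level: float = 0.95,
    method: str = "wald",
) -> tuple[float, float]:
    """Binomial proportion CI in percent, one-decimal half-away rounding.

    ``method`` is one of "wald" (default), "wilson", "clopper-pearson".
    """
    if method == "wald":
        lo, hi = wald_interval(successes, n, level)
    elif method in ("wilson", "clopper-pearson"):
        if n <= 0 or not 0 <= successes <= n:
            raise UndefinedInputError("need 0 <= successes <= n and n > 0")
        sm_method = "wilson" if method == "wilson" else "beta"
        lo, hi = proportion_confint(successes, n, alpha=1 - level, method=sm_method)
    else:
        raise UndefinedInputError(f"unknown CI method {method!r}")
    return (
        round_half_away(100.0 * max(0.0, lo), 1),
        round_half_away(100.0 * min(1.0, hi), 1),
    )


@dataclass(frozen=True)
class ValidationResult:
    """Audit outcome for one stratum."""

    stratum: str  # "verified" or "unverified"
    n_reviewed: int
    n_false_positive: int
    accuracy_percent: float
    ci_low_percent: float
    ci_high_percent: float
    confidence_level: float


def audit_precision(
    flagged_ids: Iterable[str],
    labels: Mapping[str, bool],
    *,
    stratum: str = "unverified",
    fraction: float = 0.05,
    seed: int = 0,
    level: float = 0.95,
    method: str = "wald",
) -> ValidationResult:
    """Estimate precision of a flagged set from labeled ground truth.

    ``labels`` maps account_id -> True if truly a physician. The sample of
    size round(fraction * N) is reviewed against the labels; accuracy and
    its CI are reported in percent.
    """
    sample = sample_for_audit(flagged_ids, fraction, seed)
    missing = [aid for aid in sample if aid not in labels]
    if missing:
        raise MissingLabelError(missing)
    n = len(sample)
    n_fp = sum(1 for aid in sample if not labels[aid])
    if n == 0:
        return ValidationResult(stratum, 0, 0, float("nan"),
                                float("nan"), float("nan"), level)
    lo, hi = proportion_ci(n - n_fp, n, level, method)
    return ValidationResult(
        stratum=stratum,
        n_reviewed=n,
        n_false_positive=n_fp,
        accuracy_percent=compute_accuracy(n, n_fp),
        ci_low_percent=lo,
        ci_high_percent=hi,
        confidence_level=level,
    )


def validate_outcomes(
    physician_ids: Iterable[str],
    verified_ids: Iterable[str],
    labels: Mapping[str, bool],
    *,
    fraction: float = 0.05,
    seed: int = 0,
    level: float = 0.95,
    method: str = "wald",
) -> list[ValidationResult]:
    """Two-stratum validation: verified fully reviewed, unverified sampled."""
    physician_ids = set(physician_ids)
    verified = sorted(physician_ids & set(verified_ids))
    unverified = sorted(physician_ids - set(verified))
    results = []
    if verified:
        results.append(
            audit_precision(
                verified, labels, stratum="verified", fraction=1.0,
                seed=seed, level=level, method=method,
            )
        )
    if unverified:
        results.append(
            audit_precision(
                unverified, labels, stratum="unverified", fraction=fraction,
                seed=seed, level=level, method=method,
            )
        )
    return results


@dataclass(frozen=True)
class BatchAudit:
    batch_index: int
    n: int
    n_false_positive: int
    fp_rate_percent: float
    below_threshold: bool


def audit_loop(
    classified_tweets: Sequence,
    labels: Mapping[str, bool],
    batch: int = 1000,
    threshold_percent: float = 5.0,
) -> list[BatchAudit]:
    """Batchwise false-positive audit of a classified tweet stream.

    Mirrors the manual refinement loop: review tweets in order, ``batch`` at
    a time, and report each batch's false-positive rate and whether it is
    strictly below the threshold. The rule set is never mutated; rule
    editing stays a human decision.

    ``classified_tweets`` may be tweet records (``.account_id`` used) or raw
    account ids. A final partial batch is audited at its actual size.
    """
    if batch < 1:
        raise UndefinedInputError("batch must be >= 1")
    ids = [getattr(t, "account_id", t) for t in classified_tweets]
    missing = sorted({aid for aid in ids if aid not in labels})
    if missing:
        raise MissingLabelError(missing)
    results = []
    for b, start in enumerate(range(0, len(ids), batch)):
        chunk = ids[start : start + batch]
        n_fp = sum(1 for aid in chunk if not labels[aid])
        rate = round_half_away(100.0 * n_fp / len(chunk), 1)
        results.append(
            BatchAudit(
                batch_index=b,
                n=len(chunk),
                n_false_positive=n_fp,
                fp_rate_percent=rate,
                below_threshold=rate < threshold_percent,
            )
        )
        logger.info(
            "audit batch %d: %d/%d false positives (%.1f%%), below %.1f%%: %s",
            b, n_fp, len(chunk), rate, threshold_percent, rate < threshold_percent,
        )
    return results
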