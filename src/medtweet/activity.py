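"""Longitudinal activity metrics for the classified physician cohort.

Per calendar year (UTC) and per stratum ("all", "verified"): tweet counts,
unique accounts tweeting, new accounts (first in-window appearance), and mean
tweets per account. "New" means the account's earliest tweet in the analysis
window falls in that year; account-creation dates are not available in tweet
exports, so a ``lookback`` set of previously seen account ids can be supplied
to avoid labelling the whole first year "new".
"""

from __future__ import annotations

import math
from collections.abc import Collection, Iterable

import pandas as pd

from .errors import UndefinedInputError
from .records import TweetRecord
from .utils import round_half_away

ACTIVITY_COLUMNS = [
    "stratum",
    "year",
    "n_tweets",
    "n_unique_accounts",
    "n_new_accounts",
    "mean_tweets_per_account",
]


def mean_tweets_per_account(n_tweets: int, n_accounts: int) -> float:
    """Tweets per account, one decimal, half-away-from-zero."""
    if n_accounts <= 0:
        raise UndefinedInputError("n_accounts must be > 0")
    return round_half_away(n_tweets / n_accounts, 1)


def percent_change(baseline: float, final: float) -> float:
    """100 * (final - baseline) / baseline, one decimal, sign preserved."""
    if baseline <= 0:
        raise UndefinedInputError("baseline must be > 0")
    return round_half_away(100.0 * (final - baseline) / baseline, 1)


def yearly_activity(
    tweets: Iterable[TweetRecord],
    physician_ids: Collection[str],
    years: tuple[int, int],
    lookback: Collection[str] = (),
) -> pd.DataFrame:
    """One row per (stratum, year) of activity metrics.

    Emits zero-count rows (mean reported as NaN) for years with no tweets so
    the output always covers the full window.
    """
    y0, y1 = years
    physician_ids = set(physician_ids)
    lookback = set(lookback)
    window = [
        t
        for t in tweets
        if t.account_id in physician_ids and y0 <= t.timestamp.year <= y1
    ]
    rows = []
    for stratum in ("all", "verified"):
        subset = window if stratum == "all" else [t for t in window if t.verified]
        first_year: dict[str, int] = {}
        for t in subset:
            y = t.timestamp.year
            aid = t.account_id
            if aid not in first_year or y < first_year[aid]:
                first_year[aid] = y
        for year in range(y0, y1 + 1):
            yr = [t for t in subset if t.timestamp.year == year]
            accounts = {t.account_id for t in yr}
            new = {
                aid
                for aid in accounts
                if first_year[aid] == year and aid not in lookback
            }
            mean = (
                mean_tweets_per_account(len(yr), len(accounts))
                if accounts
                else math.nan
            )
            rows.append((stratum, year, len(yr), len(accounts), len(new), mean))
    return pd.DataFrame(rows, columns=ACTIVITY_COLUMNS)


def activity_table(activity: pd.DataFrame) -> pd.DataFrame:
    """Report-shaped pivot: metric rows by year columns, one block per stratum."""
    blocks = []
    for stratum, grp in activity.groupby("stratum", sort=True):
        piv = (
            grp.set_index("year")[
                [
                    "n_tweets",
                    "n_unique_accounts",
                    "n_new_accounts",
                    "mean_tweets_per_account",
                ]
            ]
            .T.rename_axis("metric")
            .reset_index()
        )
        piv.insert(0, "stratum", stratum)
        blocks.append(piv)
    if not blocks:
        return pd.DataFrame(columns=["stratum", "metric"])
    return pd.concat(blocks, ignore_index=True)
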