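"""Hashtag extraction, yearly tallies, top-k ranking, and theme aggregation.

A hashtag occurrence is one appearance of a ``#``-prefixed run of word
characters in one tweet; repeats within a tweet count repeatedly. Tallies are
per calendar year. Themes are named groups of semantically related hashtags
(e.g. "covid19 and public health") whose member counts are summed and
reported as a share of the year's total hashtag occurrences.

Hashtags are exempt from stemming and stop-word removal: stemming would
corrupt tags such as ``#meded`` or ``#covid19``. Stemming and stop-word
removal apply only to the word-frequency (word-cloud) path in
:func:`preprocess_text`.
"""

from __future__ import annotations

import re
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from ._stem import stem
from .errors import ThemeMapError
from .records import TweetRecord

# A hashtag is a maximal run of word characters (Unicode letters, digits,
# underscore) immediately after '#'; '#' alone or before punctuation is not
# a hashtag.
_HASHTAG_RE = re.compile(r"#(\w+)", re.UNICODE)
_TOKEN_RE = re.compile(r"#\w+|\w+", re.UNICODE)


def extract_hashtags(text: str) -> list[str]:
    """Return normalized (lowercased, '#'-stripped) hashtags in order.

    >>> extract_hashtags("Stay home #COVID19 #MaskUp")
    ['covid19', 'maskup']
    """
    return [m.group(1).lower() for m in _HASHTAG_RE.finditer(text)]


def preprocess_text(text: str) -> list[str]:
    """Tokenize for the word-frequency export.

    Lowercases, drops English stop words and pure numbers, Porter-stems
    ordinary words, and passes hashtags through unstemmed (with their '#').
    """
    out: list[str] = []
    for tok in _TOKEN_RE.findall(text):
        if tok.startswith("#"):
            out.append(tok.lower())
            continue
        w = tok.lower()
        if w in ENGLISH_STOP_WORDS or w.isdigit():
            continue
        out.append(stem(w))
    return out


def _year_counters(tweets: Iterable[TweetRecord]) -> dict[int, Counter]:
    counts: dict[int, Counter] = {}
    for t in tweets:
        tags = extract_hashtags(t.text)
        if tags:
            counts.setdefault(t.timestamp.year, Counter()).update(tags)
    return counts


def _ranked_frame(counter: Counter, year: int) -> pd.DataFrame:
    rows = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    distinct = sorted({c for _, c in rows}, reverse=True)
    rank_of = {c: i + 1 for i, c in enumerate(distinct)}  # dense rank
    return pd.DataFrame(
        {
            "year": year,
            "hashtag": [h for h, _ in rows],
            "count": [c for _, c in rows],
            "rank": [rank_of[c] for _, c in rows],
        }
    )


def tally_by_year(
    tweets: Iterable[TweetRecord], top_k: int | None = 100
) -> pd.DataFrame:
    """Per-year hashtag counts with dense ranks, truncated to ``top_k`` rows.

    Ties are broken by ascending lexicographic hashtag order, so the top-k
    list is always a prefix of the full ranking. ``top_k=None`` returns the
    full tally.
    """
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    counters = _year_counters(tweets)
    frames = []
    for year in sorted(counters):
        df = _ranked_frame(counters[year], year)
        if top_k is not None:
            df = df.head(top_k)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["year", "hashtag", "count", "rank"])
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ThemeMap:
    """Named themes mapping to disjoint sets of normalized hashtags."""

    themes: Mapping[str, frozenset[str]]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for theme, tags in self.themes.items():
            for tag in tags:
                if tag in seen and seen[tag] != theme:
                    raise ThemeMapError(tag, [seen[tag], theme])
                seen[tag] = theme

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ThemeMap":
        themes: dict[str, set[str]] = {}
        for theme, tag in pairs:
            tag = tag.lower().lstrip("#")
            prior = next(
                (t for t, tags in themes.items() if tag in tags and t != theme),
                None,
            )
            if prior is not None:
                raise ThemeMapError(tag, [prior, theme])
            themes.setdefault(theme, set()).add(tag)
        return cls({t: frozenset(tags) for t, tags in themes.items()})

    @classmethod
    def from_file(cls, path) -> "ThemeMap":
        """Load ``theme<TAB>hashtag`` rows; '#'-comment and blank lines skipped."""
        pairs = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                theme, tag = line.split("\t", 1)
                pairs.append((theme.strip(), tag.strip()))
        return cls.from_pairs(pairs)

    @classmethod
    def default(cls) -> "ThemeMap":
        ref = resources.files("medtweet.data").joinpath("themes.tsv")
        with resources.as_file(ref) as path:
            return cls.from_file(path)

    def theme_of(self, hashtag: str) -> str | None:
        tag = hashtag.lower().lstrip("#")
        for theme, tags in self.themes.items():
            if tag in tags:
                return theme
        return None


def assign_themes(
    tallies: pd.DataFrame,
    themes: ThemeMap,
    *,
    top_k: int | None = 100,
    top_k_only: bool = True,
) -> pd.DataFrame:
    """Aggregate full (untruncated) yearly tallies into theme shares.

    The denominator for a year is its total hashtag occurrences (all tags,
    never truncated). With ``top_k_only`` (the default) member counts are
    summed over the year's top-``top_k`` hashtags only; otherwise over all.
    Percent is the theme count over the denominator, one decimal,
    half-away-from-zero.
    """
    from .utils import round_half_away

    cols = ["year", "theme", "count", "percent", "denominator"]
    if tallies.empty or not themes.themes:
        return pd.DataFrame(columns=cols)
    rows = []
    for year, grp in tallies.groupby("year", sort=True):
        denominator = int(grp["count"].sum())
        eligible = grp
        if top_k_only and top_k is not None:
            eligible = grp.sort_values(
                ["count", "hashtag"], ascending=[False, True]
            ).head(top_k)
        counts = dict(zip(eligible["hashtag"], eligible["count"]))
        for theme in sorted(themes.themes):
            c = int(sum(counts.get(tag, 0) for tag in themes.themes[theme]))
            pct = (
                round_half_away(100.0 * c / denominator, 1)
                if denominator
                else 0.0
            )
            rows.append((int(year), theme, c, pct, denominator))
    return pd.DataFrame(rows, columns=cols)


def word_frequencies(tweets: Iterable[TweetRecord]) -> pd.DataFrame:
    """Per-year token frequencies over :func:`preprocess_text` output."""
    counters: dict[int, Counter] = {}
    for t in tweets:
        toks = preprocess_text(t.text)
        if toks:
            counters.setdefault(t.timestamp.year, Counter()).update(toks)
    rows = []
    for year in sorted(counters):
        for token, count in sorted(
            counters[year].items(), key=lambda kv: (-kv[1], kv[0])
        ):
            rows.append((year, token, count))
    return pd.DataFrame(rows, columns=["year", "token", "count"])
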