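"""Core record types: one account profile, one tweet.

A corpus is a pair ``(accounts, tweets)`` where every tweet's ``account_id``
resolves to exactly one :class:`AccountProfile`. Synthetic corpora carry a
ground-truth ``true_label`` (and the generator's ``synthetic_kind``); corpora
from real exports leave both ``None``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from datetime import datetime, timezone
from typing import Any

PHYSICIAN = "physician"
NON_PHYSICIAN = "non_physician"


@dataclass(frozen=True, slots=True)
class AccountProfile:
    """One Twitter-style account: the unit of classification."""

    account_id: str
    handle: str          # begins with "@"
    display_name: str
    bio: str
    verified: bool
    country: str         # ISO-3166 alpha-2, e.g. "US"
    true_label: str | None = None      # synthetic corpora only
    synthetic_kind: str | None = None  # generator bookkeeping, synthetic only

    def to_json_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_json_dict(cls, d: dict[str, Any]) -> "AccountProfile":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True, slots=True)
class TweetRecord:
    """One tweet: the atomic input unit of the pipeline."""

    tweet_id: str
    account_id: str
    text: str
    timestamp: datetime  # timezone-aware, UTC
    language: str        # BCP-47 primary subtag, e.g. "en"
    country: str         # ISO-3166 alpha-2
    verified: bool       # copied from the authoring account

    def to_json_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["timestamp"] = self.timestamp.astimezone(timezone.utc).isoformat()
        return d

    @classmethod
    def from_json_dict(cls, d: dict[str, Any]) -> "TweetRecord":
        d = dict(d)
        ts = d["timestamp"]
        if isinstance(ts, str):
            d["timestamp"] = datetime.fromisoformat(ts).astimezone(timezone.utc)
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})
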