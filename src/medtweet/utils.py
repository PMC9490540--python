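"""Small shared helpers: rounding and token-boundary matching."""

from __future__ import annotations

import functools
import re
from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Python's builtin ``round`` uses banker's rounding; reported percentages
    here (accuracy rates, means, shares) use the half-away-from-zero
    convention instead, so 94.45 -> 94.5 and -0.05 -> -0.1.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@functools.lru_cache(maxsize=4096)
def token_sequence_pattern(term: str) -> re.Pattern[str]:
    """Compile a case-insensitive whole-token(-sequence) pattern for ``term``.

    ``physician`` matches in "ID physician here" but not in "physicianship";
    multi-word terms such as ``plastic surgery`` match across whitespace.
    """
    parts = [re.escape(p) for p in term.split()]
    body = r"\s+".join(parts)
    return re.compile(rf"(?<!\w){body}(?!\w)", re.IGNORECASE)


def contains_token_sequence(text: str, term: str) -> bool:
    return bool(token_sequence_pattern(term).search(text))
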