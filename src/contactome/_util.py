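"""Small shared helpers: pair normalization and printed-percentage rounding."""

from __future__ import annotations

import math


def normalize_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered (sorted) form of a protein-identifier pair.

    Identifiers are whitespace-stripped and case-preserved; no alias resolution.
    """
    a, b = str(a).strip(), str(b).strip()
    return (a, b) if a <= b else (b, a)


def round_half_away(x: float) -> int:
    """Round half away from zero (1382/1880 -> 74%, 577/494 -> 117%)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def percent(numerator: float, denominator: float) -> int:
    """Integer percentage as printed in summary accounting tables."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator)
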