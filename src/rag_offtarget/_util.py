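"""Small shared helpers: DNA alphabet handling and the report rounding rule."""

from __future__ import annotations

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (24/7 -> 3.4, 0.25 -> 0.3 at 1 digit).

    Python's built-in round() is banker's rounding; reports here follow the
    half-away-from-zero convention used for all printed percentages and means.
    """
    factor = 10**ndigits
    scaled = x * factor
    if scaled >= 0:
        rounded = int(scaled + 0.5)
    else:
        rounded = -int(-scaled + 0.5)
    return rounded / factor


def fmt_one_decimal(x: float) -> str:
    """Render a number with exactly one decimal, half away from zero."""
    return f"{round_half_away(x, 1):.1f}"
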