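"""Coordinate-convention utilities.

Every on-disk format touched by this package commits to a different
convention: SAM and GTF are 1-based inclusive, BED is 0-based half-open,
and all in-memory positions in this package are 0-based. Conversions are
centralised here so each one happens exactly once, at the format boundary.
"""

from __future__ import annotations


def one_based_to_zero_half_open(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open.

    >>> one_based_to_zero_half_open(25, 47)
    (24, 47)
    """
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based inclusive interval [{start}, {end}]")
    return start - 1, end


def zero_half_open_to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    if start < 0 or end <= start:
        raise ValueError(f"invalid 0-based half-open interval [{start}, {end})")
    return start + 1, end


def one_based_pos_to_zero(pos: int) -> int:
    """1-based single position -> 0-based index."""
    if pos < 1:
        raise ValueError(f"invalid 1-based position {pos}")
    return pos - 1


def zero_pos_to_one_based(pos: int) -> int:
    """0-based index -> 1-based single position."""
    if pos < 0:
        raise ValueError(f"invalid 0-based position {pos}")
    return pos + 1
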