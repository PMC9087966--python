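"""Promoter coordinate arithmetic.

Biological promoter coordinates place the transcription start site at +1
and admit no position 0, so the interval [-80, +20] spans exactly 100
nucleotides.  All public functions here convert between such coordinates
and 0-based string offsets relative to an *anchor*, the promoter
coordinate of a sequence's first nucleotide (−80 for a core promoter).
"""
from __future__ import annotations

#: Core promoter bounds used throughout: 80 nt upstream, 20 nt downstream.
CORE_START = -80
CORE_END = +20
CORE_LENGTH = 100


def coord_rank(p: int) -> int:
    """Map a promoter coordinate to a gapless integer rank (+1 -> 0)."""
    if p == 0:
        raise ValueError("promoter coordinates have no position 0")
    return p - 1 if p > 0 else p


def offset_from_anchor(anchor: int, p: int) -> int:
    """0-based offset of coordinate ``p`` in a sequence anchored at ``anchor``."""
    return coord_rank(p) - coord_rank(anchor)


def span_nt(start: int, end: int) -> int:
    """Number of nucleotides covered by the closed interval [start, end]."""
    n = coord_rank(end) - coord_rank(start) + 1
    if n < 1:
        raise ValueError(f"empty coordinate span [{start}, {end}]")
    return n
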