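"""Seeded synthetic-sequence generator.

Emulates the shape of the study corpus without downloads: promoter-like
positives carry an AT-rich BRE+TATA element planted at a configurable
position on an i.i.d. background of configurable GC content; TSS-centered
source records (1001 nt, TSS at index 501) embed such a core at −80..+20.

The generator reproduces positional composition only — no codon structure,
repeats, or organism-specific dinucleotide bias beyond GC fraction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coords import CORE_START, offset_from_anchor
from .corpus import PromoterRecord

#: IUPAC degeneracy classes used in motif templates.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "W": "AT", "S": "GC", "N": "ACGT",
}

#: Default planted element: 2-nt BRE (s) + TATA-box template, covering
#: −34..−25 so the default −32..−25 classifier slice reads the TATA part.
DEFAULT_MOTIF = "SSTTATAWWW"
DEFAULT_MOTIF_POSITION = -34


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic sequence set."""

    n: int = 500
    length_nt: int = 100
    gc_background: float = 0.5
    motif: str = DEFAULT_MOTIF
    motif_position: int = DEFAULT_MOTIF_POSITION
    rng_seed: int = 0
    anchor: int = CORE_START
    consensus: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_background <= 1.0):
            raise ValueError("gc_background must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be positive")
        m = self.motif.upper()
        if any(c not in IUPAC for c in m):
            raise ValueError(f"motif {self.motif!r} has non-IUPAC characters")

    def motif_offset(self) -> int:
        off = offset_from_anchor(self.anchor, self.motif_position)
        if off < 0 or off + len(self.motif) > self.length_nt:
            raise ValueError(
                f"motif of {len(self.motif)} nt at {self.motif_position} "
                f"overflows the {self.length_nt}-nt sequence "
                f"(anchor {self.anchor})"
            )
        return off


def _background_letters(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _instantiate_motif(rng: np.random.Generator, motif: str, consensus: bool) -> str:
    out = []
    for c in motif.upper():
        choices = IUPAC[c]
        if len(choices) == 1 or consensus:
            out.append(choices[0])
        else:
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def generate_background(spec: SynthSpec) -> list[PromoterRecord]:
    """i.i.d. background sequences: P(G)=P(C)=gc/2, P(A)=P(T)=(1−gc)/2."""
    rng = np.random.default_rng(spec.rng_seed)
    return [
        PromoterRecord(
            id=f"synth_bg_{i:04d}",
            seq=_background_letters(rng, spec.length_nt, spec.gc_background),
            label="unknown",
        )
        for i in range(spec.n)
    ]


def generate_promoters(spec: SynthSpec) -> list[PromoterRecord]:
    """Background sequences with the IUPAC motif instantiated and planted.

    Degenerate motif letters are drawn per record (within-motif variance),
    unless ``consensus`` freezes the first alternative everywhere.
    """
    off = spec.motif_offset()
    rng = np.random.default_rng(spec.rng_seed)
    records = []
    for i in range(spec.n):
        bg = _background_letters(rng, spec.length_nt, spec.gc_background)
        motif = _instantiate_motif(rng, spec.motif, spec.consensus)
        seq = bg[:off] + motif + bg[off + len(motif):]
        records.append(
            PromoterRecord(id=f"synth_prom_{i:04d}", seq=seq, label="promoter")
        )
    return records


def generate_tss_sources(spec: SynthSpec, flank: int = 500) -> list[PromoterRecord]:
    """TSS-centered source records (2·flank+1 nt, TSS at index flank+1).

    A generated core promoter occupies coordinates −80..+20 around the
    center, so core extraction recovers it byte-identically; the +21..+120
    downstream-control window contains pure background.
    """
    if flank < 100:
        raise ValueError("flank must cover the core promoter (>= 100 nt)")
    if spec.length_nt != 100 or spec.anchor != CORE_START:
        raise ValueError("TSS-centered sources embed a standard 100-nt core")
    total = 2 * flank + 1
    tss_offset = flank + 1
    cores = generate_promoters(spec)
    rng = np.random.default_rng((spec.rng_seed + 777_000_001) % (2**31))
    records = []
    core_start0 = tss_offset - 81  # 0-based index of coordinate -80
    for i, core in enumerate(cores):
        bg = _background_letters(rng, total, spec.gc_background)
        seq = bg[:core_start0] + core.seq + bg[core_start0 + len(core.seq):]
        records.append(
            PromoterRecord(
                id=f"synth_tss_{i:04d}", seq=seq, label="promoter",
                tss_offset=tss_offset,
            )
        )
    return records
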