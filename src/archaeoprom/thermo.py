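"""DNA duplex stability (DDS) encoding.

A nucleotide sequence is converted into a numeric profile by sliding a
dinucleotide window along it and assigning each window the nearest-neighbor
duplex free energy of that base-pair doublet (kcal/mol at 37 °C).  AT-rich
stretches such as TATA-boxes are the least stable (least negative) regions
of the profile, which is what makes archaeal basal transcription-factor
binding sites stand out against genomic background.

The default energy table is the unified nearest-neighbor ΔG°37 set; it is
Watson–Crick symmetric, so a profile and the profile of the reverse
complement are mirror images.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .coords import offset_from_anchor

DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in "ACGT" for b in "ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U to T (RNA-style input is tolerated on ingest)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class DinucleotideTable:
    """16-entry map from dinucleotide (5'→3') to duplex free energy (kcal/mol).

    Invariants: exactly the 16 ACGT dinucleotides as keys, all values finite
    and negative (duplex formation is stabilizing).  Watson–Crick symmetry
    (value(XY) == value(revcomp(XY))) holds for the default table and is
    checked with a warning, not an error, so alternate parameter sets that
    break it deliberately can still be loaded.
    """

    values: dict[str, float]
    source_label: str = ""

    def __post_init__(self) -> None:
        keys = set(self.values)
        missing = set(DINUCLEOTIDES) - keys
        extra = keys - set(DINUCLEOTIDES)
        if missing:
            raise ValueError(f"missing dinucleotide(s): {sorted(missing)}")
        if extra:
            raise ValueError(f"unexpected dinucleotide key(s): {sorted(extra)}")
        for k, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite free energy for {k}: {v}")
            if v >= 0:
                raise ValueError(
                    f"free energy for {k} is {v}; duplex formation must be "
                    "stabilizing (negative kcal/mol)"
                )
        asym = [d for d in DINUCLEOTIDES if self.values[d] != self.values[revcomp(d)]]
        if asym:
            warnings.warn(
                f"table '{self.source_label}' breaks Watson-Crick symmetry "
                f"for: {asym}",
                stacklevel=2,
            )

    def __getitem__(self, dinucleotide: str) -> float:
        return self.values[dinucleotide]

    @property
    def min_value(self) -> float:
        return min(self.values.values())

    @property
    def max_value(self) -> float:
        return max(self.values.values())


@dataclass
class DDSProfile:
    """Ordered per-dinucleotide free energies for one sequence.

    ``values[i]`` is the energy of the doublet starting at nucleotide ``i``;
    the profile of an n-nt sequence has n−1 entries.  ``anchor`` is the
    promoter coordinate of the first nucleotide (−80 for a core promoter)
    or ``None`` when the sequence carries no coordinate system, in which
    case window positions are plain 0-based indices.
    """

    values: np.ndarray
    anchor: int | None = None

    def __len__(self) -> int:
        return len(self.values)


def load_table(path: str | Path = "default") -> DinucleotideTable:
    """Load a dinucleotide free-energy table.

    ``"default"`` selects the packaged unified nearest-neighbor ΔG°37 table.
    Otherwise ``path`` must point to a two-column whitespace-delimited text
    file (dinucleotide, kcal/mol); ``#`` lines are comments and a header row
    is tolerated.
    """
    if path == "default":
        ref = resources.files("archaeoprom.data").joinpath("unified_nn_dg37.tsv")
        text = ref.read_text()
        label = "unified nearest-neighbor dG37"
    else:
        text = Path(path).read_text()
        label = str(path)
    values: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"malformed table row: {line!r}")
        key = normalize_sequence(parts[0])
        if len(key) != 2 or any(c not in "ACGT" for c in key):
            # tolerate a single header row
            if not values and not _is_float(parts[1]):
                continue
            raise ValueError(f"invalid dinucleotide {parts[0]!r}")
        if not _is_float(parts[1]):
            raise ValueError(f"non-numeric value for {key}: {parts[1]!r}")
        values[key] = float(parts[1])
    return DinucleotideTable(values=values, source_label=label)


def _is_float(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def encode_sequence(
    seq: str,
    table: DinucleotideTable,
    *,
    anchor: int | None = None,
    policy: str = "strict",
) -> DDSProfile:
    """Encode a sequence into its DDS profile (Eq. of the sliding window).

    ``policy="strict"`` (default) rejects non-ACGT characters; ``"skip"``
    marks profile positions touching an ambiguous base as NaN so callers can
    exclude the affected statistics.
    """
    s = normalize_sequence(seq)
    if len(s) < 2:
        raise ValueError(f"sequence of length {len(s)} is too short to encode")
    if policy not in ("strict", "skip"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    vals = np.empty(len(s) - 1, dtype=float)
    for i in range(len(s) - 1):
        d = s[i : i + 2]
        try:
            vals[i] = table[d]
        except KeyError:
            if policy == "strict":
                bad = i if s[i] not in "ACGT" else i + 1
                raise ValueError(
                    f"disallowed character {s[bad]!r} at position {bad + 1}"
                ) from None
            vals[i] = np.nan
    return DDSProfile(values=vals, anchor=anchor)


def window_sum(profile: DDSProfile, start: int, width_nt: int) -> float:
    """Free-energy sum over a ``width_nt``-nucleotide window.

    ``start`` is a promoter coordinate when the profile carries an anchor,
    otherwise a 0-based nucleotide index.  An 8-nt window covers 7 profile
    values; their sum is the slice statistic used downstream.
    """
    if width_nt < 2:
        raise ValueError(f"window width {width_nt} nt is below the 2-nt minimum")
    if profile.anchor is None:
        i0 = start
    else:
        i0 = offset_from_anchor(profile.anchor, start)
    i1 = i0 + width_nt - 1  # number of dinucleotide values covered
    if i0 < 0 or i1 > len(profile.values):
        raise ValueError(
            f"window start={start} width={width_nt} nt maps to profile "
            f"indices [{i0}, {i1}) outside [0, {len(profile.values)})"
        )
    return float(np.sum(profile.values[i0:i1]))


def positional_mean_profile(
    records: Sequence, table: DinucleotideTable, *, policy: str = "strict"
) -> np.ndarray:
    """Per-position mean free energy across a set of equal-length sequences.

    Accepts plain strings or any objects with ``seq`` (and optionally ``id``)
    attributes.  Returns a vector of length n−1 for n-nt input.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot average an empty sequence set")
    seqs = [getattr(r, "seq", r) for r in records]
    ids = [getattr(r, "id", f"record_{i}") for i, r in enumerate(records)]
    n = len(seqs[0])
    bad = [ids[i] for i, s in enumerate(seqs) if len(s) != n]
    if bad:
        raise ValueError(f"unequal sequence lengths for record(s): {bad}")
    mat = np.vstack(
        [encode_sequence(s, table, policy=policy).values for s in seqs]
    )
    if policy == "skip":
        return np.asarray(np.nanmean(mat, axis=0))
    return mat.mean(axis=0)
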