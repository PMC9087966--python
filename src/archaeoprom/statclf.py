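"""Interval-based statistical promoter classifier.

The TATA-box/BRE neighbourhood of an archaeal core promoter is markedly
less stable than background DNA.  Summing the dinucleotide free energies
over a fixed 8-nt slice of the core promoter (7 values; default slice
−32..−25, covering the BRE+TATA element) yields a per-sequence statistic
whose promoter-set mean x̄ and standard deviation σ define the closed
classification interval [x̄ − σ, x̄ + σ]: a sequence is called a promoter
iff its slice statistic falls inside the interval.  A model fitted on one
organism can be applied unchanged to another (cross-organism transfer).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .coords import CORE_START, CORE_END, offset_from_anchor, coord_rank
from .corpus import PromoterRecord
from .thermo import DinucleotideTable, encode_sequence, window_sum


@dataclass(frozen=True)
class SliceSpec:
    """Position-specific slice of the core promoter.

    ``start`` is the promoter coordinate of the slice's first nucleotide
    (TSS = +1, no position 0).  The default contiguous 8-nt slice at
    −32..−25 covers the 2-nt BRE extremity plus the 6-nt TATA-box and
    yields exactly 7 dinucleotide values.  ``gapped=True`` selects the
    alternate reading of the element: 2 nt (BRE) + a skipped 2-nt spacer +
    6 nt (TATA) taken from a 10-nt window and concatenated before encoding,
    which also yields 7 values.
    """

    start: int = -32
    width_nt: int = 8
    gapped: bool = False

    def __post_init__(self) -> None:
        if self.width_nt < 2:
            raise ValueError("slice width must be at least 2 nt")
        if self.gapped and self.width_nt != 8:
            raise ValueError("gapped mode is defined for the 8-nt BRE+TATA slice")

    @property
    def span_nt(self) -> int:
        """Nucleotides of sequence the slice occupies (10 when gapped)."""
        return self.width_nt + 2 if self.gapped else self.width_nt

    @property
    def end(self) -> int:
        """Promoter coordinate of the last nucleotide covered."""
        r = coord_rank(self.start) + self.span_nt - 1
        return r + 1 if r >= 0 else r


@dataclass
class StatModel:
    """Fitted promoter interval (mean ± sd of the slice statistic)."""

    slice: SliceSpec
    mean: float
    sd: float
    lower: float
    upper: float
    training_n: int
    organism_tag: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")
        if self.training_n < 2:
            raise ValueError("a model needs at least 2 training sequences")
        if not (np.isclose(self.lower, self.mean - self.sd)
                and np.isclose(self.upper, self.mean + self.sd)):
            raise ValueError("interval bounds must equal mean ± sd")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["slice"] = asdict(self.slice)
        d["kind"] = "stat"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StatModel":
        d = dict(d)
        d.pop("kind", None)
        d["slice"] = SliceSpec(**d["slice"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json" else yaml.safe_dump(self.to_dict()))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "StatModel":
        path = Path(path)
        d = (json.loads(path.read_text()) if path.suffix == ".json"
             else yaml.safe_load(path.read_text()))
        return cls.from_dict(d)


def slice_statistic(
    record: PromoterRecord | str,
    slice_spec: SliceSpec,
    table: DinucleotideTable,
    *,
    anchor: int = CORE_START,
    policy: str = "strict",
) -> float:
    """DDS sum over the slice of a core promoter (kcal/mol).

    The record is assumed anchored at ``anchor`` (−80 for a 100-nt core).
    For the default 8-nt slice this sums 7 dinucleotide values.
    """
    seq = getattr(record, "seq", record)
    if slice_spec.end > CORE_END and anchor == CORE_START:
        raise ValueError(
            f"slice [{slice_spec.start}, {slice_spec.end}] extends past the "
            f"+{CORE_END} core boundary"
        )
    i0 = offset_from_anchor(anchor, slice_spec.start)
    if i0 < 0 or i0 + slice_spec.span_nt > len(seq):
        raise ValueError(
            f"slice at {slice_spec.start} (span {slice_spec.span_nt} nt) "
            f"falls outside the {len(seq)}-nt sequence"
        )
    if slice_spec.gapped:
        window = seq[i0 : i0 + 10]
        element = window[0:2] + window[4:10]  # BRE + TATA, spacer skipped
        profile = encode_sequence(element, table, policy=policy)
        return float(np.sum(profile.values))
    profile = encode_sequence(seq, table, anchor=anchor, policy=policy)
    return window_sum(profile, slice_spec.start, slice_spec.width_nt)


def fit_interval(
    promoters,
    slice_spec: SliceSpec,
    table: DinucleotideTable,
    *,
    organism_tag: str = "",
) -> StatModel:
    """Fit the promoter interval: mean ± sample sd of the slice statistic."""
    stats = np.array(
        [slice_statistic(r, slice_spec, table) for r in promoters], dtype=float
    )
    if len(stats) < 2:
        raise ValueError("interval fitting needs at least 2 promoter records")
    mean = float(stats.mean())
    sd = float(stats.std(ddof=1))
    return StatModel(
        slice=slice_spec,
        mean=mean,
        sd=sd,
        lower=mean - sd,
        upper=mean + sd,
        training_n=len(stats),
        organism_tag=organism_tag,
    )


def classify_stat(
    record: PromoterRecord | str,
    model: StatModel,
    table: DinucleotideTable,
    *,
    anchor: int = CORE_START,
) -> str:
    """Label a sequence ``promoter`` iff its statistic lies in the closed interval."""
    s = slice_statistic(record, model.slice, table, anchor=anchor)
    return "promoter" if model.lower <= s <= model.upper else "non_promoter"


def cross_apply(model: StatModel, records, table: DinucleotideTable) -> list[str]:
    """Apply a (possibly foreign-organism) model to a dataset without refitting."""
    return [classify_stat(r, model, table) for r in records]
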