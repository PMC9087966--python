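"""Promoter annotation of unannotated upstream regions.

Fixed-length upstream regions (RSAT-style, e.g. 400 nt per gene) are
screened with a panel of trained models.  The 3' terminus of each region is
treated as the transcription start site (+1) — archaeal transcripts are
frequently leaderless — so a model's core-promoter slice coordinates map
directly onto the region.  Two localization modes exist:

* ``anchored`` — read the slice at each model's own coordinates;
* ``scan``     — slide a window over a search region (default −50..−15) and
  take the position with the maximal (least stable) DDS sum, the TATA
  signature, ties broken toward the TSS.

A region is annotated as a promoter only if *every* model in the panel
votes promoter (logical AND; relaxable via ``min_votes``).  Accepted calls
can be compared against verified promoter sets with a Kruskal–Wallis rank
test over positional mean profiles.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coords import coord_rank
from .corpus import PromoterRecord
from .statclf import SliceSpec, StatModel, slice_statistic
from .annclf import MLPModel, featurize, predict
from .thermo import DinucleotideTable, encode_sequence, positional_mean_profile, window_sum


@dataclass
class AnnotationCall:
    """Per-region outcome of the consensus screen."""

    seq_id: str
    candidate_site: int            # promoter coordinate of the slice start
    per_model_votes: dict[str, str]
    final: str                     # promoter / non_promoter
    statistic: float               # DDS sum over the evaluated slice (kcal/mol)
    ann_output: dict[str, float] = field(default_factory=dict)
    seq_len: int = 0
    slice_width: int = 8


def _upstream_anchor(seq_len: int) -> int:
    # last nucleotide is the TSS (+1); the first is at -(seq_len - 1)
    return -(seq_len - 1)


def locate_site(
    upstream_seq: str,
    table: DinucleotideTable,
    slice_width: int = 8,
    search_region: tuple[int, int] = (-50, -15),
) -> int:
    """Most TATA-like window start within the search region.

    Returns the promoter coordinate (3'-terminus = +1) of the
    ``slice_width``-nt window with the maximal DDS sum.  Ties break toward
    the TSS-proximal position.  Content outside the search region never
    affects the result.
    """
    seq = getattr(upstream_seq, "seq", upstream_seq)
    anchor = _upstream_anchor(len(seq))
    lo, hi = search_region
    n_positions = coord_rank(hi) - coord_rank(lo) + 1
    if n_positions < slice_width:
        raise ValueError(
            f"search region [{lo}, {hi}] ({n_positions} nt) is shorter than "
            f"the {slice_width}-nt slice"
        )
    profile = encode_sequence(seq, table, anchor=anchor)
    best_start, best_sum = None, -np.inf
    # iterate TSS-proximal first so strict improvement keeps proximal ties
    for r in range(coord_rank(hi) - slice_width + 1, coord_rank(lo) - 1, -1):
        start = r + 1 if r >= 0 else r
        s = window_sum(profile, start, slice_width)
        if s > best_sum:
            best_start, best_sum = start, s
    return best_start


def _model_tags(models) -> list[str]:
    tags, seen = [], set()
    for i, m in enumerate(models):
        t = getattr(m, "organism_tag", "") or getattr(m, "tag", "")
        kind = "stat" if isinstance(m, StatModel) else "ann"
        t = f"{kind}:{t}" if t else f"{kind}:{i}"
        while t in seen:
            t += "'"
        seen.add(t)
        tags.append(t)
    return tags


def consensus_call(
    upstream_record: PromoterRecord | str,
    models,
    table: DinucleotideTable,
    mode: str = "anchored",
    *,
    min_votes: int | None = None,
    search_region: tuple[int, int] = (-50, -15),
    threshold: float = 0.5,
) -> AnnotationCall:
    """Vote every model on one upstream region and AND the verdicts."""
    models = list(models)
    if not models:
        raise ValueError("consensus requires at least one model")
    widths = {m.slice.width_nt for m in models}
    if len(widths) != 1:
        raise ValueError(f"models disagree on slice width: {sorted(widths)}")
    width = widths.pop()
    if mode not in ("anchored", "scan"):
        raise ValueError(f"unknown mode {mode!r}")

    seq = getattr(upstream_record, "seq", upstream_record)
    seq_id = getattr(upstream_record, "id", "seq")
    anchor = _upstream_anchor(len(seq))
    site = (locate_site(seq, table, width, search_region)
            if mode == "scan" else None)

    votes: dict[str, str] = {}
    ann_out: dict[str, float] = {}
    statistic = np.nan
    tags = _model_tags(models)
    for tag, m in zip(tags, models):
        spec = (m.slice if mode == "anchored"
                else SliceSpec(site, m.slice.width_nt, m.slice.gapped))
        if isinstance(m, StatModel):
            s = slice_statistic(seq, spec, table, anchor=anchor)
            votes[tag] = "promoter" if m.lower <= s <= m.upper else "non_promoter"
            statistic = s
        else:
            x = featurize(seq, spec, table, anchor=anchor)
            labels, raw = predict(m, x, threshold)
            votes[tag] = "promoter" if labels[0] == 1 else "non_promoter"
            ann_out[tag] = float(raw[0])
        if np.isnan(statistic):
            statistic = slice_statistic(seq, spec, table, anchor=anchor)
    need = len(models) if min_votes is None else min_votes
    n_yes = sum(1 for v in votes.values() if v == "promoter")
    final = "promoter" if n_yes >= need else "non_promoter"
    call_site = site if site is not None else models[0].slice.start
    return AnnotationCall(
        seq_id=seq_id, candidate_site=call_site, per_model_votes=votes,
        final=final, statistic=statistic, ann_output=ann_out,
        seq_len=len(seq), slice_width=width,
    )


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H (midranks, tie-corrected) with χ² p on k−1 df.

    The degenerate case of all values identical across all groups yields
    H = 0, p = 1 with a warning rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("Kruskal-Wallis groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across groups; H = 0")
        return 0.0, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def profile_compare(
    verified_sets: dict,
    candidate_sets: dict,
    table: DinucleotideTable,
    region: tuple[int, int] = (-40, -1),
    *,
    anchor: int = -80,
) -> dict:
    """Compare positional mean DDS profiles of sequence sets over a region.

    Each set (name → equal-length records on a common anchor) is reduced to
    its per-position mean profile restricted to ``region``; a
    Kruskal–Wallis test across the sets' positional means follows.
    """
    sets = {**verified_sets, **candidate_sets}
    if any(not list(v) for v in sets.values()):
        raise ValueError("all sets must be non-empty")
    lo, hi = region
    i0 = coord_rank(lo) - coord_rank(anchor)
    n_vals = coord_rank(hi) - coord_rank(lo)  # dinucleotides fully inside
    if n_vals < 1:
        raise ValueError(f"region [{lo}, {hi}] covers no dinucleotide step")
    means: dict[str, np.ndarray] = {}
    for name, records in sets.items():
        full = positional_mean_profile(records, table)
        if i0 < 0 or i0 + n_vals > len(full):
            raise ValueError(
                f"region [{lo}, {hi}] falls outside the profile of set {name!r}"
            )
        means[name] = full[i0 : i0 + n_vals]
    H, p = kruskal_wallis(list(means.values()))
    return {"means": means, "H": H, "p": p}


def write_annotation(calls, path: str | Path, format: str = "tsv") -> None:
    """Write annotation calls as TSV (all calls) or GFF3 (accepted promoters)."""
    calls = list(calls)
    path = Path(path)
    if format == "tsv":
        rows = []
        for c in calls:
            row = {
                "id": c.seq_id,
                "final": c.final,
                "site": c.candidate_site,
                "statistic": c.statistic,
            }
            for tag, v in c.per_model_votes.items():
                row[f"vote[{tag}]"] = v
            for tag, v in c.ann_output.items():
                row[f"output[{tag}]"] = v
            rows.append(row)
        cols = ["id", "final", "site", "statistic"]
        df = pd.DataFrame(rows, columns=cols + sorted(
            {k for r in rows for k in r} - set(cols)))
        df.to_csv(path, sep="\t", index=False)
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for c in calls:
                if c.final != "promoter":
                    continue
                idx0 = (c.seq_len - 1) + coord_rank(c.candidate_site)
                start, end = idx0 + 1, idx0 + c.slice_width
                votes = ",".join(
                    f"{t}={v}" for t, v in sorted(c.per_model_votes.items()))
                fh.write("\t".join([
                    c.seq_id, "archaeoprom", "promoter",
                    str(start), str(end), f"{c.statistic:.2f}",
                    "+", ".", f"ID=promoter_{c.seq_id};votes={votes}",
                ]) + "\n")
    else:
        raise ValueError(f"unknown annotation format {format!r}")
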