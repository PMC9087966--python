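"""FASTA ingest, core-promoter extraction and control-set generation.

Promoter collections arrive as TSS-centered records (1001 nt with the
transcription start site mapped) or as pre-trimmed 100-nt core promoters
spanning −80..+20.  Three engineered negative sets stress a classifier:

* ``shuffled``   — a uniform permutation of the core promoter's letters;
* ``downstream`` — the +21..+120 window of the source record, transcribed
  sequence with no promoter activity;
* ``blocks``     — the core cut into 20 blocks of 5 nt of which 12 randomly
  chosen blocks swap positions (contents intact), so motifs inside unmoved
  blocks survive and the negative set is deliberately promoter-like.

All generators conserve mononucleotide composition exactly and are
bit-reproducible under a fixed seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coords import CORE_LENGTH
from .thermo import normalize_sequence

LABELS = ("promoter", "shuffled", "downstream", "blocks", "unknown")


@dataclass
class PromoterRecord:
    """One sequence with its class label and optional TSS anchor.

    ``tss_offset`` is the 1-based index of the +1 nucleotide within the
    source sequence (501 for the standard 1001-nt deposit records); it is
    ``None`` for pre-trimmed cores and controls.
    """

    id: str
    seq: str
    label: str = "unknown"
    tss_offset: int | None = None

    def __post_init__(self) -> None:
        self.seq = normalize_sequence(self.seq)
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.label not in LABELS:
            raise ValueError(
                f"record {self.id!r}: label {self.label!r} not in {LABELS}"
            )


def read_fasta(path: str | Path, *, label: str = "unknown") -> list[PromoterRecord]:
    """Read a FASTA file into records, preserving input order.

    The id is the first whitespace token of each header; a ``label=`` key in
    the description overrides the ``label`` argument.  Duplicate ids are
    suffix-deduplicated with a warning.
    """
    records: list[PromoterRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"record {rec.id!r} has a zero-length sequence")
        rec_label = label
        for token in rec.description.split():
            if token.startswith("label="):
                rec_label = token[len("label="):]
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}.{seen[rid]}"
            warnings.warn(f"duplicate id {rid!r} renamed to {new_id!r}")
            rid = new_id
        else:
            seen[rid] = 0
        records.append(PromoterRecord(id=rid, seq=seq, label=rec_label))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA, storing the label in the header."""
    records = list(records)
    if not records:
        warnings.warn(f"writing an empty FASTA file to {path}")
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=f"label={r.label}")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def extract_core(record: PromoterRecord) -> PromoterRecord:
    """Extract the 100-nt core promoter (−80..+20) around the mapped TSS.

    With the TSS nucleotide at 1-based source index ``tss_offset``, the core
    covers source indices ``tss_offset−80 .. tss_offset+19`` (inclusive,
    1-based): 80 upstream positions, the TSS, and 19 further downstream.
    """
    if record.tss_offset is None:
        raise ValueError(f"record {record.id!r} has no TSS offset")
    t = record.tss_offset
    need_up, need_down = 80, 19
    if t - need_up < 1 or t + need_down > len(record.seq):
        raise ValueError(
            f"record {record.id!r}: core extraction needs source indices "
            f"[{t - need_up}, {t + need_down}] but sequence spans "
            f"[1, {len(record.seq)}]"
        )
    core = record.seq[t - need_up - 1 : t + need_down]
    assert len(core) == CORE_LENGTH
    return PromoterRecord(id=record.id, seq=core, label="promoter")


def control_shuffle(record: PromoterRecord, rng_seed: int) -> PromoterRecord:
    """Full mononucleotide shuffle of a core promoter (label ``shuffled``)."""
    rng = np.random.default_rng(rng_seed)
    letters = np.array(list(record.seq))
    shuffled = "".join(rng.permutation(letters))
    return PromoterRecord(id=record.id, seq=shuffled, label="shuffled")


def control_downstream(record: PromoterRecord) -> PromoterRecord:
    """Transcribed-region control: the 100-nt window at +21..+120.

    The source window starts one position past the +20 core boundary;
    trimmed to the core length so positives and negatives match.
    """
    if record.tss_offset is None:
        raise ValueError(f"record {record.id!r} has no TSS offset")
    t = record.tss_offset
    start, end = t + 20, t + 119  # 1-based source indices of +21..+120
    if end > len(record.seq):
        raise ValueError(
            f"record {record.id!r}: downstream control needs source index "
            f"{end} but sequence has length {len(record.seq)}"
        )
    return PromoterRecord(
        id=record.id, seq=record.seq[start - 1 : end], label="downstream"
    )


def control_blocks(
    record: PromoterRecord,
    n_blocks: int = 20,
    block_len: int = 5,
    k_shuffled: int = 12,
    rng_seed: int = 0,
    *,
    within_blocks: bool = False,
) -> PromoterRecord:
    """Block-shuffle control preserving most local motifs (label ``blocks``).

    The sequence is cut into ``n_blocks`` blocks of ``block_len`` nt;
    ``k_shuffled`` block positions are chosen uniformly at random and the
    chosen blocks are permuted among those positions with contents intact.
    ``within_blocks=True`` instead shuffles the letters inside each chosen
    block, leaving all block positions fixed.
    """
    if len(record.seq) != n_blocks * block_len:
        raise ValueError(
            f"record {record.id!r}: length {len(record.seq)} != "
            f"{n_blocks} blocks x {block_len} nt"
        )
    if k_shuffled > n_blocks:
        raise ValueError(f"cannot shuffle {k_shuffled} of {n_blocks} blocks")
    rng = np.random.default_rng(rng_seed)
    blocks = [
        record.seq[i * block_len : (i + 1) * block_len] for i in range(n_blocks)
    ]
    chosen = sorted(rng.choice(n_blocks, size=k_shuffled, replace=False))
    if within_blocks:
        for i in chosen:
            blocks[i] = "".join(rng.permutation(list(blocks[i])))
    else:
        perm = rng.permutation(k_shuffled)
        moved = [blocks[chosen[p]] for p in perm]
        for slot, blk in zip(chosen, moved):
            blocks[slot] = blk
    return PromoterRecord(id=record.id, seq="".join(blocks), label="blocks")
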