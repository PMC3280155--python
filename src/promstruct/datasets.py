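"""Sequence/annotation I/O and strand-aware promoter-window extraction.

Conventions
-----------
* TSS input is 6-column BED, 0-based half-open.  For ``+`` records the TSS
  is ``start``; for ``-`` records it is ``end - 1``.
* Windows span ``up`` bases upstream through ``down`` bases downstream of
  the TSS *on the annotated strand* (minus-strand windows are reverse
  complemented), giving ``up + down + 1`` bases.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profiles import WINDOW_DOWNSTREAM, WINDOW_UPSTREAM

__all__ = [
    "TssRecord",
    "LabeledSequenceSet",
    "read_fasta",
    "write_fasta",
    "read_tss_bed",
    "extract_window",
    "extract_windows",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PROMOTER = "promoter"
NON_PROMOTER = "non-promoter"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TssRecord:
    """One annotated transcription start site."""

    chrom: str
    pos: int  # 0-based coordinate of the TSS base
    strand: str = "+"
    id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.pos}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class LabeledSequenceSet:
    """Equal-length windows with a total promoter/non-promoter labelling."""

    sequences: dict[str, str] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if set(self.sequences) != set(self.labels):
            raise ValueError("sequence ids and label ids differ")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        bad = {l for l in self.labels.values()} - {PROMOTER, NON_PROMOTER}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @classmethod
    def from_parts(
        cls,
        positives: Mapping[str, str] | Iterable[str],
        negatives: Mapping[str, str] | Iterable[str],
    ) -> "LabeledSequenceSet":
        def as_map(seqs, prefix):
            if isinstance(seqs, Mapping):
                return dict(seqs)
            return {f"{prefix}{i}": s for i, s in enumerate(seqs)}

        pos = as_map(positives, "pos")
        neg = as_map(negatives, "neg")
        if set(pos) & set(neg):
            raise ValueError("positive and negative ids overlap")
        sequences = {**pos, **neg}
        labels = {i: PROMOTER for i in pos} | {i: NON_PROMOTER for i in neg}
        return cls(sequences=sequences, labels=labels)

    def ids(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered id -> uppercase sequence map."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_tss_bed(path: str | Path) -> list[TssRecord]:
    """Parse a 6-column BED file of TSS annotations.

    BED is 0-based half-open; the TSS is ``start`` on ``+`` and ``end - 1``
    on ``-``.  Malformed lines raise ``ValueError`` naming the line number.
    """
    records: list[TssRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >=6 BED columns, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end_i <= start_i:
                raise ValueError(f"{path}:{lineno}: end <= start")
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            pos = start_i if strand == "+" else end_i - 1
            records.append(TssRecord(chrom=chrom, pos=pos, strand=strand, id=name))
    return records


def extract_window(
    genome_seq: str,
    tss: TssRecord,
    up: int = WINDOW_UPSTREAM,
    down: int = WINDOW_DOWNSTREAM,
) -> str:
    """Extract the strand-aware ``up``..``down`` window around one TSS.

    Raises ``ValueError`` if the window does not fit inside *genome_seq*;
    batch extraction (:func:`extract_windows`) downgrades that to a logged
    skip.
    """
    if tss.strand == "+":
        lo, hi = tss.pos - up, tss.pos + down + 1
    else:
        lo, hi = tss.pos - down, tss.pos + up + 1
    if lo < 0 or hi > len(genome_seq):
        raise ValueError(
            f"window [{lo}, {hi}) for TSS {tss.id or tss.pos} out of bounds "
            f"for sequence of length {len(genome_seq)}"
        )
    window = genome_seq[lo:hi].upper()
    return reverse_complement(window) if tss.strand == "-" else window


def extract_windows(
    genome: Mapping[str, str],
    tss_records: Iterable[TssRecord],
    up: int = WINDOW_UPSTREAM,
    down: int = WINDOW_DOWNSTREAM,
    deduplicate: bool = True,
) -> dict[str, str]:
    """Extract windows for many TSSs, skipping out-of-bounds records.

    Duplicate (chrom, pos, strand) records are collapsed to the first
    occurrence when *deduplicate* is set.
    """
    seen: set[tuple[str, int, str]] = set()
    out: dict[str, str] = {}
    for i, tss in enumerate(tss_records):
        key = (tss.chrom, tss.pos, tss.strand)
        if deduplicate and key in seen:
            continue
        seen.add(key)
        if tss.chrom not in genome:
            logger.warning("skipping TSS %s: unknown chrom %s", tss.id or i, tss.chrom)
            continue
        try:
            window = extract_window(genome[tss.chrom], tss, up=up, down=down)
        except ValueError as exc:
            logger.warning("skipping TSS %s: %s", tss.id or i, exc)
            continue
        name = tss.id or f"{tss.chrom}:{tss.pos}:{tss.strand}"
        if name in out:
            name = f"{name}.{i}"
        out[name] = window
    return out
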