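"""Sequence input/output and per-residue masking.

Sequences are plain amino-acid strings carrying a parallel boolean mask
track; a ``True`` mask bit excludes that residue from every downstream
window (enumeration, matching and background counting all share the same
"is this window usable" predicate).  Masks come from three places: the
lowercase-masking FASTA dialect, explicit interval annotations (BED-style
0-based half-open coordinates), and automatic masking of non-standard
residue letters (B, J, O, U, X, Z, ``*``), which are retained verbatim but
never contribute to a window.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)


@dataclasses.dataclass(eq=False)
class SequenceRecord:
    """One identified protein sequence with its boolean mask track.

    ``residues`` is uppercase after normalization; ``mask`` has the same
    length, ``True`` marking excluded positions.
    """

    id: str
    residues: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.residues) != self.mask.shape[0]:
            raise ValueError(
                f"record {self.id!r}: mask length {self.mask.shape[0]} "
                f"!= sequence length {len(self.residues)}"
            )

    @classmethod
    def from_string(cls, id: str, raw: str,
                    mask: Optional[Sequence[bool]] = None) -> "SequenceRecord":
        """Build a record from raw FASTA text, normalizing case.

        Lowercase letters are uppercased with their mask bit set (the
        lowercase-masking dialect); non-standard letters are kept but
        force-masked.
        """
        if not raw:
            raise ValueError(f"record {id!r} has no residues")
        bits = np.zeros(len(raw), dtype=bool) if mask is None else np.asarray(mask, bool).copy()
        for i, ch in enumerate(raw):
            if ch.islower():
                bits[i] = True
        residues = raw.upper()
        for i, ch in enumerate(residues):
            if ch not in _STANDARD_SET:
                bits[i] = True
        return cls(id=id, residues=residues, mask=bits)

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass
class SequenceSet:
    """Ordered collection of records with unique ids."""

    records: list[SequenceRecord]
    role: str = "query"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id: {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def get(self, id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == id:
                return rec
        raise KeyError(id)


@dataclasses.dataclass(frozen=True)
class MaskAnnotation:
    """Intervals to mask on one sequence, 0-based half-open."""

    sequence_id: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for start, end in self.intervals:
            if not 0 <= start < end:
                raise ValueError(
                    f"invalid interval ({start}, {end}) on {self.sequence_id!r}"
                )


def read_fasta(path: str | Path, role: str = "query") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`, preserving order.

    Lowercase residues are uppercased with their mask bit set.  Raises on
    empty files, duplicate ids, records without residues, and content that
    is not FASTA (reported with the offending line number).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: not FASTA format at line {lineno}: {line.strip()[:40]!r}"
                    )
                break
        else:
            raise ValueError(f"{path}: no sequences")
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord.from_string(entry.id, str(entry.seq)))
    if not records:
        raise ValueError(f"{path}: no sequences")
    return SequenceSet(records=records, role=role)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    """Write records as FASTA, rendering masked positions lowercase."""
    with open(path, "w") as fh:
        for rec in seqs:
            chars = [c.lower() if m else c for c, m in zip(rec.residues, rec.mask)]
            fh.write(f">{rec.id}\n")
            body = "".join(chars)
            for i in range(0, len(body), 70):
                fh.write(body[i:i + 70] + "\n")


def read_mask_bed(path: str | Path) -> list[MaskAnnotation]:
    """Read mask intervals from a BED-like TSV: sequence_id, start, end."""
    by_id: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 tab-separated fields")
            sid, start, end = fields[0], int(fields[1]), int(fields[2])
            by_id.setdefault(sid, []).append((start, end))
    return [MaskAnnotation(sid, tuple(ivs)) for sid, ivs in by_id.items()]


def apply_mask_annotations(seqs: SequenceSet,
                           masks: Iterable[MaskAnnotation]) -> SequenceSet:
    """Return a new set with mask bits set over the union of intervals.

    Residues are unchanged; the operation is idempotent and insensitive to
    annotation order.  Unknown sequence ids and out-of-range intervals are
    errors.
    """
    by_id = {rec.id: rec for rec in seqs}
    new_masks = {rec.id: rec.mask.copy() for rec in seqs}
    for ann in masks:
        if ann.sequence_id not in by_id:
            raise ValueError(f"mask annotation for unknown sequence id: {ann.sequence_id!r}")
        length = len(by_id[ann.sequence_id])
        for start, end in ann.intervals:
            if end > length:
                raise ValueError(
                    f"interval ({start}, {end}) out of range for "
                    f"{ann.sequence_id!r} (length {length})"
                )
            new_masks[ann.sequence_id][start:end] = True
    records = [
        SequenceRecord(id=rec.id, residues=rec.residues, mask=new_masks[rec.id])
        for rec in seqs
    ]
    return SequenceSet(records=records, role=seqs.role)


_TABLE_COLUMNS = ("pattern", "k", "l", "q", "b", "WC", "p_raw", "p_adj")


def write_motif_table(table, path: str | Path) -> None:
    """Write a ranked motif list as TSV.

    One row per motif: pattern, k, l, q, b, WC, p_raw, p_adj, with
    P-values in scientific notation (7 significant digits).
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for s in table:
            fh.write(
                f"{s.pattern}\t{s.k}\t{s.l}\t{s.q}\t{s.b}\t{s.wc}\t"
                f"{s.p_raw:.6e}\t{s.p_adj:.6e}\n"
            )


def read_motif_table(path: str | Path):
    """Read a TSV written by :func:`write_motif_table` back into MotifStats."""
    from .scoring import MotifStats  # local import to avoid a cycle

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TABLE_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(MotifStats(
                pattern=f[0], k=int(f[1]), l=int(f[2]), q=int(f[3]),
                b=int(f[4]), wc=int(f[5]), p_raw=float(f[6]), p_adj=float(f[7]),
            ))
    return out
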