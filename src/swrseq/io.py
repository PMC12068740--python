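"""Interval, genome and coverage I/O in the plain-text formats the pipeline touches.

All coordinates are 0-based half-open (BED convention). Nucleosome dyads are
stored as single-base intervals ``[d, d+1)``. Fragment input is 3+ column BED of
already-paired fragments; alignment happens upstream of this package.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "GenomeSequence",
    "FragmentCollection",
    "BedFormatError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
]


class BedFormatError(ValueError):
    """Malformed BED input; message carries the 1-based line number."""


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional BED extras."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand is not None and self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeSequence:
    """Uppercase nucleotide sequences keyed by chromosome name."""

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = {name: s.upper() for name, s in seqs.items()}
        bad = {
            name
            for name, s in self._seqs.items()
            if set(s) - set("ACGTN")
        }
        if bad:
            raise ValueError(f"non-ACGTN characters in chromosome(s): {sorted(bad)}")

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def keys(self):
        return self._seqs.keys()

    def items(self):
        return self._seqs.items()

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self._seqs.items()}

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence under an interval; raises if out of bounds."""
        seq = self._seqs[interval.chrom]
        if interval.end > len(seq):
            raise IndexError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {len(seq)}"
            )
        return seq[interval.start : interval.end]


class FragmentCollection:
    """An ordered set of paired-end fragments as genomic intervals."""

    def __init__(self, fragments: Iterable[GenomicInterval]):
        self.fragments: list[GenomicInterval] = list(fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.fragments)

    def __getitem__(self, i):
        return self.fragments[i]

    @property
    def count(self) -> int:
        return len(self.fragments)

    def lengths(self) -> np.ndarray:
        return np.array([f.length for f in self.fragments], dtype=int)

    def length_summary(self) -> dict[str, float]:
        ls = self.lengths()
        if ls.size == 0:
            return {"count": 0, "min": np.nan, "max": np.nan, "mean": np.nan}
        return {
            "count": int(ls.size),
            "min": int(ls.min()),
            "max": int(ls.max()),
            "mean": float(ls.mean()),
        }


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into intervals, preserving file order.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped. Malformed
    lines (fewer than 3 columns, non-integer coordinates, start >= end) raise
    :class:`BedFormatError` naming the offending line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"line {lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in {".", ""}:
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] != "" else None
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
                )
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED, emitting only the columns that are populated."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            extras = [
                iv.name if iv.name is not None else ".",
                format(iv.score, "g") if iv.score is not None else ".",
                iv.strand if iv.strand is not None else ".",
            ]
            # trim trailing unset columns
            while extras and extras[-1] == ".":
                extras.pop()
            fh.write("\t".join(fields + extras) + "\n")


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file; sequences are case-folded to uppercase.

    Duplicate record names raise ``ValueError``.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence | Mapping[str, str], path: str | Path) -> None:
    if isinstance(genome, GenomeSequence):
        items = genome.items()
    else:
        items = genome.items()
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


def write_bedgraph(track, path: str | Path, *, emit_zeros: bool = True) -> None:
    """Serialize a per-base coverage track as bedGraph (run-length encoded).

    Runs of equal value collapse into one record; a write/read round trip
    reproduces the per-base vectors exactly. NaN values are rejected.
    ``emit_zeros=False`` suppresses zero-valued records.
    """
    with open(path, "w") as fh:
        for chrom in track.chroms():
            values = np.asarray(track[chrom], dtype=float)
            if np.isnan(values).any():
                raise ValueError(f"NaN in coverage track for {chrom}")
            if values.size == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v == 0 and not emit_zeros:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_bedgraph(path: str | Path, chrom_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Read a bedGraph into dense per-base vectors (one per chromosome)."""
    vectors = {name: np.zeros(length, dtype=float) for name, length in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedFormatError(f"line {lineno}: expected 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in vectors:
                raise BedFormatError(f"line {lineno}: unknown chromosome {chrom!r}")
            vectors[chrom][start:end] = value
    return vectors
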