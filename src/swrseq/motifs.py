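"""Sequence-composition machinery: dyad-anchored dinucleotide profiles,
genome baselines, homopolymer (poly(dA:dT)) tract statistics, in-frame genic
tiling and codon frequencies.

Conventions
-----------
"Top strand" means the genomic plus strand throughout; positioned-nucleosome
maps carry no orientation, and the palindromic dAdA/dTdT pattern around the
dyad is only well-defined on a fixed strand. A "dA5 site" is a *maximal* A-run
of length >= 5 counted once (a dA10 run is one dA5 site, not six sliding
occurrences). Ambiguous bases (N) break runs and are excluded from frequency
denominators.
"""

from __future__ import annotations

import dataclasses
import re
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomeSequence, GenomicInterval

__all__ = [
    "DINUCLEOTIDES",
    "CODONS",
    "DyadProfile",
    "TractStats",
    "extract_dyad_window",
    "dinuc_profile",
    "genome_dinuc_baseline",
    "count_homopolymer_runs",
    "tract_summary",
    "tile_genic_inframe",
    "codon_frequencies",
]

DINUCLEOTIDES = tuple("".join(p) for p in product("ACGT", repeat=2))
CODONS = tuple("".join(p) for p in product("ACGT", repeat=3))

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

NUC_HALF = 73  # bases on each side of the dyad in a 147-bp core


@dataclasses.dataclass
class DyadProfile:
    """Position-resolved dinucleotide frequencies over aligned sequences.

    ``freq[o, m]`` is the fraction of sequences whose top-strand dinucleotide
    starting at offset ``offsets[o]`` equals ``DINUCLEOTIDES[m]``, with the
    denominator restricted to sequences unambiguous at both bases.
    """

    offsets: np.ndarray  # dinucleotide start positions relative to the dyad
    freq: np.ndarray  # (n_offsets, 16)
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, index=self.offsets, columns=list(DINUCLEOTIDES))

    def frequency(self, motif: str) -> np.ndarray:
        return self.freq[:, DINUCLEOTIDES.index(motif.upper())]


@dataclasses.dataclass
class TractStats:
    """Per-sequence poly(dA)/poly(dT) run counts plus set-level summary."""

    min_len: int
    a_runs: np.ndarray  # per-sequence count of maximal A-runs >= min_len
    t_runs: np.ndarray
    fraction_with_tract: float  # sequences with >= 1 A- or T-run
    mean_tracts: float  # mean (A-runs + T-runs) per sequence

    @property
    def totals(self) -> np.ndarray:
        return self.a_runs + self.t_runs


def extract_dyad_window(
    genome: GenomeSequence, nuc, flank: int = 20
) -> str:
    """Top-strand sequence of length ``147 + 2*flank`` centered at a
    nucleosome dyad.

    ``nuc`` may be anything exposing ``chrom``/``dyad`` attributes or a
    ``(chrom, dyad)`` pair. No gene-strand flipping is performed. Windows
    running off the chromosome raise ``IndexError`` naming the nucleosome.
    """
    if isinstance(nuc, tuple):
        chrom, dyad = nuc
        label = f"{chrom}:{dyad}"
    else:
        chrom, dyad = nuc.chrom, nuc.dyad
        label = getattr(nuc, "id", f"{chrom}:{dyad}")
    start = dyad - NUC_HALF - flank
    end = dyad + NUC_HALF + 1 + flank
    if start < 0 or end > genome.lengths[chrom]:
        raise IndexError(f"dyad window out of bounds for nucleosome {label}")
    return genome.fetch(GenomicInterval(chrom, start, end))


def _encode(seqs: Sequence[str]) -> np.ndarray:
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    mat = np.frombuffer("".join(s.upper() for s in seqs).encode(), dtype=np.uint8)
    return _CODE[mat].reshape(len(seqs), lengths.pop())


def _positional_dinuc_freq(codes: np.ndarray) -> np.ndarray:
    """(L-1, 16) dinucleotide frequencies from an (n, L) base-code matrix."""
    a, b = codes[:, :-1], codes[:, 1:]
    valid = (a >= 0) & (b >= 0)
    pair = np.where(valid, 4 * a + b, 16)
    n_pos = pair.shape[1]
    freq = np.zeros((n_pos, 16))
    for o in range(n_pos):
        counts = np.bincount(pair[:, o], minlength=17)[:16]
        denom = counts.sum()
        if denom:
            freq[o] = counts / denom
    return freq


def dinuc_profile(seqs: Sequence[str]) -> DyadProfile:
    """Dinucleotide frequency profile of equal-length dyad-aligned sequences.

    Offsets run from ``-(L//2)`` to ``L//2 - 1`` (dinucleotide start positions
    relative to the central base, the dyad for odd-length windows).
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    codes = _encode(seqs)
    freq = _positional_dinuc_freq(codes)
    center = codes.shape[1] // 2
    offsets = np.arange(codes.shape[1] - 1) - center
    return DyadProfile(offsets=offsets, freq=freq, n_sequences=len(seqs))


def genome_dinuc_baseline(genome: GenomeSequence | Mapping[str, str]) -> np.ndarray:
    """Genome-wide dinucleotide frequencies (overlapping windows, plus strand).

    Returns a 16-vector over :data:`DINUCLEOTIDES` summing to 1; windows
    containing N are skipped.
    """
    items = genome.items()
    counts = np.zeros(16, dtype=np.int64)
    any_seq = False
    for _, seq in items:
        any_seq = True
        codes = _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
        if codes.size < 2:
            continue
        a, b = codes[:-1], codes[1:]
        valid = (a >= 0) & (b >= 0)
        pair = 4 * a[valid] + b[valid]
        counts += np.bincount(pair, minlength=16)
    if not any_seq:
        raise ValueError("empty genome")
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous dinucleotides in genome")
    return counts / total


def count_homopolymer_runs(seq: str, base: str, min_len: int) -> int:
    """Number of maximal runs of ``base`` with length >= ``min_len``.

    Each maximal run counts once regardless of how far it exceeds the
    threshold; N (or any other character) breaks a run.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    base = base.upper()
    if base not in "ACGT":
        raise ValueError("base must be one of A, C, G, T")
    pattern = re.compile(f"{base}{{{min_len},}}")
    return sum(1 for _ in pattern.finditer(seq.upper()))


def tract_summary(seqs: Sequence[str], min_len: int = 5) -> TractStats:
    """Poly(dA)/poly(dT) tract statistics over a sequence set.

    Per sequence, the tract total is the number of maximal top-strand A-runs
    plus T-runs of length >= ``min_len``. The summary reports the fraction of
    sequences with at least one tract and the mean tract total.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    a_runs = np.array([count_homopolymer_runs(s, "A", min_len) for s in seqs])
    t_runs = np.array([count_homopolymer_runs(s, "T", min_len) for s in seqs])
    totals = a_runs + t_runs
    return TractStats(
        min_len=min_len,
        a_runs=a_runs,
        t_runs=t_runs,
        fraction_with_tract=float((totals >= 1).mean()),
        mean_tracts=float(totals.mean()),
    )


def tile_genic_inframe(
    orf_seqs: Sequence[str], tile_len: int = 21
) -> tuple[list[str], np.ndarray]:
    """Cut coding sequences into consecutive in-frame tiles and profile them.

    Tiles start at codon position 0 and do not overlap; a trailing remainder
    shorter than ``tile_len`` is dropped. Returns the tiles plus the
    positional dinucleotide frequency matrix ``(tile_len - 1, 16)`` averaged
    over all tiles — codon-biased input shows 3-bp periodicity here.
    """
    if tile_len % 3 != 0:
        raise ValueError("tile_len must be a multiple of 3 (in-frame tiling)")
    tiles: list[str] = []
    for seq in orf_seqs:
        for i in range(0, (len(seq) // tile_len) * tile_len, tile_len):
            tiles.append(seq[i : i + tile_len].upper())
    if not tiles:
        return [], np.zeros((tile_len - 1, 16))
    freq = _positional_dinuc_freq(_encode(tiles))
    return tiles, freq


def codon_frequencies(orf_seqs: Sequence[str]) -> np.ndarray:
    """In-frame codon usage over all sequences, as a 64-vector over
    :data:`CODONS` summing to 1. Sequence lengths must be multiples of 3."""
    counts = np.zeros(64, dtype=np.int64)
    index = {c: i for i, c in enumerate(CODONS)}
    total = 0
    for seq in orf_seqs:
        if len(seq) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        s = seq.upper()
        for i in range(0, len(s), 3):
            codon = s[i : i + 3]
            if codon in index:
                counts[index[codon]] += 1
                total += 1
    if total == 0:
        raise ValueError("no unambiguous codons in input")
    return counts / total
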