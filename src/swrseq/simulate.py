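"""Self-contained synthetic chromatin worlds with known ground truth.

A :class:`SyntheticWorld` bundles a random genome, a non-overlapping nucleosome
map with promoter position classes (+1 / -1 / +2 / other), a set of nucleosomes
that depend on the SWR remodeler for H2A.Z deposition, and a set of "preferred"
nucleosomes carrying planted poly(dA) / poly(dT) tracts at the nucleosomal DNA
entry/exit region. Fragment samplers emulate the two assay geometries:

* two-condition ChIP (wild type vs. remodeler-null), where the null condition
  is a pure noise channel and the wild type adds a deposition effect at the
  true SWR-dependent sites;
* the in vitro streptavidin pulldown, where each fragment is partitioned into
  an eluate or flow-through (FT) fraction with logistic odds increasing in the
  nucleosome's A/T tract content and the reaction time.

Everything is deterministic under a fixed seed, so downstream callers can be
tested end-to-end without any external data.
"""

from __future__ import annotations

import dataclasses
import json
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import FragmentCollection, GenomeSequence, GenomicInterval, write_bed, write_fasta
from .motifs import count_homopolymer_runs

__all__ = [
    "WorldParams",
    "NucleosomeRecord",
    "SyntheticWorld",
    "make_world",
    "sample_chip_fragments",
    "sample_pulldown_fragments",
    "make_genic_sequences",
    "SENSE_CODONS",
]

NUC_LEN = 147  # canonical nucleosomal DNA length
DYAD_OFFSET = 73  # dyad = start + 73 for a 147-bp nucleosome

STOP_CODONS = {"TAA", "TAG", "TGA"}
#: the 61 sense codons in lexicographic order; index base for codon weights
SENSE_CODONS = tuple(
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)


@dataclasses.dataclass(frozen=True)
class NucleosomeRecord:
    """One 147-bp positioned nucleosome with its promoter position class."""

    id: str
    interval: GenomicInterval
    position_class: str  # one of {"+1", "-1", "+2", "other"}
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.interval.length != NUC_LEN:
            raise ValueError(f"nucleosome {self.id} is not {NUC_LEN} bp")
        if self.position_class not in {"+1", "-1", "+2", "other"}:
            raise ValueError(f"unknown position class {self.position_class!r}")

    @property
    def dyad(self) -> int:
        return self.interval.start + DYAD_OFFSET

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclasses.dataclass
class WorldParams:
    """Generation parameters for a synthetic world.

    Scale defaults (2 chromosomes x 200 kb, 1,000 nucleosomes at 200-bp
    spacing) keep runs desk-sized while leaving the 3% rank tails
    non-degenerate. The planted tract default is a dA10 run on the top strand
    between dyad-relative offsets -41 and -31 — the entry/exit placement that
    stimulates the remodeler — with an optionally mirrored dT10 run on the
    other half.
    """

    n_chroms: int = 2
    chrom_len: int = 200_000
    n_nucleosomes: int = 1000
    spacing: int = 200
    margin: int = 500
    frac_swr: float = 0.18
    frac_preferred: float = 0.03
    tract_len: int = 10
    tract_lo: int = -41
    tract_hi: int = -31
    mirror_prob: float = 0.5
    # ChIP channel
    base_weight: float = 5.0
    effect: float = 20.0
    noise_sd: float = 2.0
    frag_len_range: tuple[int, int] = (120, 170)
    midpoint_jitter: int = 20
    # in vitro pulldown channel (logistic partition)
    pull_alpha: float = -1.0
    pull_beta: float = 1.5
    pull_gamma: float = 0.01
    invitro_frag_len_range: tuple[int, int] = (140, 154)
    seed: int | None = None

    def validate(self) -> None:
        if self.n_chroms < 1:
            raise ValueError("need at least one chromosome")
        per_chrom = -(-self.n_nucleosomes // self.n_chroms)  # ceil
        needed = 2 * self.margin + (per_chrom - 1) * self.spacing + NUC_LEN
        if self.spacing < NUC_LEN:
            raise ValueError("spacing must be >= 147 bp so nucleosomes do not overlap")
        if needed > self.chrom_len:
            raise ValueError(
                f"cannot pack {per_chrom} nucleosomes at {self.spacing}-bp spacing "
                f"into a {self.chrom_len}-bp chromosome"
            )
        if self.tract_hi - self.tract_lo + 1 < self.tract_len:
            raise ValueError("tract placement window shorter than tract length")


@dataclasses.dataclass
class SyntheticWorld:
    """A genome, nucleosome map and the truth labels used to score recovery."""

    genome: GenomeSequence
    nucleosomes: list[NucleosomeRecord]
    truth_swr_sites: set[str]
    truth_preferred: set[str]
    tract_placements: dict[str, list[tuple[int, str]]]  # id -> [(dyad-rel offset, base)]
    params: WorldParams

    def nucleosome(self, nuc_id: str) -> NucleosomeRecord:
        return self._index[nuc_id]

    def __post_init__(self) -> None:
        self._index = {n.id: n for n in self.nucleosomes}
        ids = set(self._index)
        if not self.truth_swr_sites <= ids or not self.truth_preferred <= ids:
            raise ValueError("truth sets must be subsets of nucleosome ids")

    def nucleosome_sequence(self, nuc: NucleosomeRecord | str, flank: int = 0) -> str:
        """Top-strand sequence of the nucleosome core plus symmetric flanks."""
        rec = self.nucleosome(nuc) if isinstance(nuc, str) else nuc
        iv = rec.interval
        return self.genome.fetch(
            GenomicInterval(iv.chrom, iv.start - flank, iv.end + flank)
        )

    def tract_count(self, nuc: NucleosomeRecord | str, min_len: int = 5) -> int:
        """Number of maximal A- plus T-runs >= min_len in the 147-bp core."""
        seq = self.nucleosome_sequence(nuc)
        return count_homopolymer_runs(seq, "A", min_len) + count_homopolymer_runs(
            seq, "T", min_len
        )

    def save(self, outdir: str | Path) -> None:
        """Write the world as FASTA + BED + TSV so downstream stages consume
        only standard files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_bed(
            [
                GenomicInterval(
                    n.chrom, n.interval.start, n.interval.end,
                    name=n.id, score=0.0, strand=n.interval.strand or ".",
                )
                for n in self.nucleosomes
            ],
            outdir / "nucleosomes.bed",
        )
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("nucleosome_id\tposition_class\tgene_id\tswr_dependent\tpreferred\n")
            for n in self.nucleosomes:
                fh.write(
                    f"{n.id}\t{n.position_class}\t{n.gene_id or '.'}\t"
                    f"{int(n.id in self.truth_swr_sites)}\t"
                    f"{int(n.id in self.truth_preferred)}\n"
                )
        with open(outdir / "params.json", "w") as fh:
            json.dump(dataclasses.asdict(self.params), fh, indent=2, default=list)


def _assign_classes(i: int) -> tuple[str, int]:
    """Cycle nucleosomes through pseudo-gene units of five.

    Each unit carries a -1 / +1 / +2 promoter trio followed by two gene-body
    ("other") nucleosomes; the unit index doubles as the gene id.
    """
    unit, pos = divmod(i, 5)
    cls = ("-1", "+1", "+2", "other", "other")[pos]
    return cls, unit


def make_world(params: WorldParams | None = None, seed: int = 0) -> SyntheticWorld:
    """Build a deterministic synthetic world.

    Background sequence is i.i.d. uniform over {A,C,G,T}. Every preferred
    nucleosome receives a planted top-strand A-run of ``params.tract_len``
    starting within dyad-relative offsets ``[tract_lo, tract_hi]`` on the left
    half; with probability ``mirror_prob`` a mirrored T-run is additionally
    planted on the right half.
    """
    params = params or WorldParams()
    params.validate()
    rng = np.random.default_rng(seed)

    chrom_names = [f"chr{i + 1}" for i in range(params.n_chroms)]
    genome_arrays = {
        name: rng.integers(0, 4, size=params.chrom_len, dtype=np.int8)
        for name in chrom_names
    }

    nucleosomes: list[NucleosomeRecord] = []
    per_chrom = -(-params.n_nucleosomes // params.n_chroms)
    count = 0
    for ci, chrom in enumerate(chrom_names):
        for j in range(per_chrom):
            if count >= params.n_nucleosomes:
                break
            start = params.margin + j * params.spacing
            cls, unit = _assign_classes(count)
            strand = "+" if unit % 2 == 0 else "-"
            gene_id = f"g{unit}" if cls != "other" else f"g{unit}"
            nucleosomes.append(
                NucleosomeRecord(
                    id=f"nuc{count}",
                    interval=GenomicInterval(
                        chrom, start, start + NUC_LEN, name=f"nuc{count}", strand=strand
                    ),
                    position_class=cls,
                    gene_id=gene_id,
                )
            )
            count += 1
    if not nucleosomes:
        raise ValueError("empty nucleosome map")

    ids = [n.id for n in nucleosomes]
    n_swr = int(round(params.frac_swr * len(ids)))
    n_pref = int(round(params.frac_preferred * len(ids)))
    truth_swr = set(rng.choice(ids, size=n_swr, replace=False)) if n_swr else set()
    truth_pref = set(rng.choice(ids, size=n_pref, replace=False)) if n_pref else set()

    base_codes = {"A": 0, "C": 1, "G": 2, "T": 3}
    placements: dict[str, list[tuple[int, str]]] = {}
    max_start = params.tract_hi - params.tract_len + 1  # dyad-relative
    index = {n.id: n for n in nucleosomes}
    for nid in sorted(truth_pref):
        rec = index[nid]
        arr = genome_arrays[rec.chrom]
        offset = int(rng.integers(params.tract_lo, max_start + 1))
        start = rec.dyad + offset
        arr[start : start + params.tract_len] = base_codes["A"]
        placed = [(offset, "A")]
        if rng.random() < params.mirror_prob:
            # mirror the run onto the right half: offsets o..o+L-1 -> -o-L+1..-o
            m_start = rec.dyad - (offset + params.tract_len - 1)
            arr[m_start : m_start + params.tract_len] = base_codes["T"]
            placed.append((m_start - rec.dyad, "T"))
        placements[nid] = placed

    lookup = np.array(list("ACGT"))
    genome = GenomeSequence(
        {name: "".join(lookup[arr]) for name, arr in genome_arrays.items()}
    )
    world = SyntheticWorld(
        genome=genome,
        nucleosomes=nucleosomes,
        truth_swr_sites=truth_swr,
        truth_preferred=truth_pref,
        tract_placements=placements,
        params=dataclasses.replace(params, seed=seed),
    )
    return world


def _chip_weights(
    world: SyntheticWorld, condition: str, rng: np.random.Generator
) -> np.ndarray:
    """Per-nucleosome sampling weights: shared base + SWR effect (WT only)
    + Gaussian noise, truncated at zero."""
    p = world.params
    if condition not in {"WT", "mutant"}:
        raise ValueError("condition must be 'WT' or 'mutant'")
    w = np.full(len(world.nucleosomes), p.base_weight, dtype=float)
    if condition == "WT" and p.effect:
        is_truth = np.array(
            [n.id in world.truth_swr_sites for n in world.nucleosomes]
        )
        w[is_truth] += p.effect
    if p.noise_sd:
        w = w + rng.normal(0.0, p.noise_sd, size=w.size)
    return np.clip(w, 0.0, None)


def _draw_fragments(
    world: SyntheticWorld,
    nuc_idx: np.ndarray,
    rng: np.random.Generator,
    len_range: tuple[int, int],
) -> list[GenomicInterval]:
    p = world.params
    lo, hi = len_range
    lengths = rng.integers(lo, hi + 1, size=nuc_idx.size)
    jitter = rng.integers(-p.midpoint_jitter, p.midpoint_jitter + 1, size=nuc_idx.size)
    frags = []
    chrom_lens = world.genome.lengths
    for k, i in enumerate(nuc_idx):
        rec = world.nucleosomes[i]
        mid = rec.dyad + int(jitter[k])
        length = int(lengths[k])
        start = mid - length // 2
        start = max(0, min(start, chrom_lens[rec.chrom] - length))
        frags.append(GenomicInterval(rec.chrom, start, start + length))
    return frags


def sample_chip_fragments(
    world: SyntheticWorld,
    condition: str,
    replicate: int,
    n_frags: int,
    seed: int = 0,
) -> FragmentCollection:
    """Draw ChIP fragments for one condition/replicate.

    Fragment nucleosome-of-origin is multinomial over the per-nucleosome
    weights; midpoints jitter uniformly around the dyad and lengths are
    discrete-uniform over ``params.frag_len_range``. WT and mutant share base
    weights, so with ``effect = 0`` the two conditions are exchangeable.
    """
    if n_frags < 1:
        raise ValueError("n_frags must be >= 1")
    if not world.nucleosomes:
        raise ValueError("empty nucleosome map")
    cond_code = {"WT": 0, "mutant": 1}
    if condition not in cond_code:
        raise ValueError("condition must be 'WT' or 'mutant'")
    rng = np.random.default_rng([seed, replicate, cond_code[condition]])
    w = _chip_weights(world, condition, rng)
    total = w.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    idx = rng.choice(len(w), size=n_frags, p=w / total)
    return FragmentCollection(
        _draw_fragments(world, idx, rng, world.params.frag_len_range)
    )


def sample_pulldown_fragments(
    world: SyntheticWorld,
    time_point: float,
    n_frags: int,
    seed: int = 0,
    replicate: int = 1,
) -> tuple[FragmentCollection, FragmentCollection]:
    """Draw in vitro reaction fragments and partition them into (eluate, FT).

    Each fragment's nucleosome is drawn uniformly; it lands in the eluate with
    probability ``sigmoid(alpha + beta * tract_count + gamma * time_point)``
    where ``tract_count`` is the number of A/T runs >= 5 in the 147-bp core.
    ``beta > 0`` encodes the remodeler's tract preference. Counts always
    conserve: ``len(eluate) + len(ft) == n_frags``.
    """
    if time_point <= 0:
        raise ValueError("time_point must be positive (minutes)")
    if not world.nucleosomes:
        raise ValueError("empty nucleosome map")
    p = world.params
    rng = np.random.default_rng([seed, replicate, int(time_point), 2])
    tract_counts = np.array(
        [world.tract_count(n, min_len=5) for n in world.nucleosomes], dtype=float
    )
    logit = p.pull_alpha + p.pull_beta * tract_counts + p.pull_gamma * time_point
    p_eluate = 1.0 / (1.0 + np.exp(-logit))
    idx = rng.integers(0, len(world.nucleosomes), size=n_frags)
    in_eluate = rng.random(n_frags) < p_eluate[idx]
    frags = _draw_fragments(world, idx, rng, p.invitro_frag_len_range)
    eluate = FragmentCollection(f for f, keep in zip(frags, in_eluate) if keep)
    ft = FragmentCollection(f for f, keep in zip(frags, in_eluate) if not keep)
    return eluate, ft


def make_genic_sequences(
    n_genes: int,
    codon_weights: Sequence[float] | None = None,
    seed: int = 0,
    gene_len: int = 300,
) -> list[tuple[str, str]]:
    """Generate in-frame coding sequences with i.i.d. codon usage.

    ``codon_weights`` is a 61-vector over :data:`SENSE_CODONS` (stop codons are
    excluded from gene bodies); ``None`` means uniform usage. ``gene_len`` must
    be a multiple of 3.
    """
    if gene_len % 3 != 0:
        raise ValueError("gene_len must be a multiple of 3")
    if codon_weights is None:
        weights = np.ones(len(SENSE_CODONS))
    else:
        weights = np.asarray(codon_weights, dtype=float)
    if weights.shape != (len(SENSE_CODONS),):
        raise ValueError(f"codon_weights must have length {len(SENSE_CODONS)}")
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("codon_weights must be nonnegative with positive sum")
    rng = np.random.default_rng(seed)
    probs = weights / weights.sum()
    codons = np.array(SENSE_CODONS)
    n_codons = gene_len // 3
    out = []
    for g in range(n_genes):
        picks = rng.choice(codons.size, size=n_codons, p=probs)
        out.append((f"orf{g}", "".join(codons[picks])))
    return out
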