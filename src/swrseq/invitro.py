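"""Quantifying the remodeler's in vitro substrate preference.

The streptavidin pulldown partitions a reaction into an eluate (nucleosomes
that received the tagged H2A.Z-H2B dimer) and a flow-through (FT).
"Z-enrichment" at a nucleosome is the eluate-minus-FT difference of RPM
coverage; ranking nucleosomes by consensus Z-enrichment and taking symmetric
3% tails defines preferred/unpreferred substrate sets, which are then tested
for overlap enrichment against in vivo H2A.Z sites and refined at +1
nucleosomes by k-means clustering of dyad-anchored profiles.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.cluster import KMeans

from .chip import CoverageTrack, count_at_nucleosomes
from .simulate import NucleosomeRecord
from .stats import ZTestResult, proportion_ztest

__all__ = [
    "ProfileMatrix",
    "z_enrichment",
    "consensus_enrichment",
    "rank_classify",
    "replicate_r2",
    "persistence_filter",
    "build_profile_matrix",
    "kmeans_plus1",
    "overlap_enrichment",
]


def z_enrichment(
    eluate_track: CoverageTrack,
    ft_track: CoverageTrack,
    nucs: Sequence[NucleosomeRecord],
) -> pd.Series:
    """Per-nucleosome Z-enrichment: eluate minus FT normalized coverage.

    Both tracks must be RPM-normalized over the same genome; the value per
    nucleosome is the difference of mean per-base coverage over the 147-bp
    core. Swapping the tracks negates every value.
    """
    if eluate_track.lengths != ft_track.lengths:
        raise ValueError("eluate and FT tracks cover different genomes")
    return (
        count_at_nucleosomes(eluate_track, nucs) - count_at_nucleosomes(ft_track, nucs)
    ).rename("z_enrichment")


def consensus_enrichment(replicate_values: Sequence[pd.Series]) -> pd.Series:
    """Replicate consensus = mean of per-replicate Z-enrichment values."""
    if not replicate_values:
        raise ValueError("need at least one replicate")
    return pd.concat(replicate_values, axis=1).mean(axis=1).rename("z_enrichment")


def rank_classify(
    values: pd.Series,
    nucs: Sequence[NucleosomeRecord],
    tail_frac: float = 0.03,
) -> tuple[list[str], list[str]]:
    """Split the ranked universe into (preferred, unpreferred) tail sets.

    The tail size is ``m = round(tail_frac * N)``; the top ``m`` nucleosomes by
    consensus Z-enrichment are preferred, the bottom ``m`` unpreferred. Ties
    are broken by ascending genomic coordinate within a single total ranking,
    so the two sets are always disjoint and the result is deterministic and
    invariant under any strictly monotone transform of the values.
    """
    if not 0 < tail_frac < 0.5:
        raise ValueError("tail_frac must lie in (0, 0.5)")
    coord = {n.id: (n.chrom, n.interval.start) for n in nucs}
    missing = [i for i in values.index if i not in coord]
    if missing:
        raise ValueError(f"values carry ids without nucleosome records: {missing[:3]}")
    m = int(round(tail_frac * len(values)))
    if len(values) < 2 * m:
        raise ValueError("universe too small for the requested tails")
    order = sorted(
        values.index, key=lambda i: (-values[i], coord[i][0], coord[i][1])
    )
    return order[:m], order[-m:][::-1]


def replicate_r2(values_rep1, values_rep2) -> float:
    """Squared Pearson correlation between replicate value vectors."""
    x = np.asarray(values_rep1, dtype=float)
    y = np.asarray(values_rep2, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("replicates must be equal length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in replicate vectors")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a replicate vector")
    r = pearsonr(x, y).statistic
    return float(r * r)


def persistence_filter(
    per_timepoint_sets: Sequence[Iterable[str]], min_times: int = 2
) -> set[str]:
    """Ids present in at least ``min_times`` of the per-time-point sets."""
    if not per_timepoint_sets:
        raise ValueError("need at least one set")
    counts = Counter()
    for s in per_timepoint_sets:
        counts.update(set(s))
    return {i for i, c in counts.items() if c >= min_times}


@dataclasses.dataclass
class ProfileMatrix:
    """Per-base Z-enrichment profiles anchored at +1 nucleosome dyads.

    Rows are nucleosomes, columns dyad-relative offsets ``-W..W``; rows from
    genes on the minus strand are reversed so downstream is always rightward.
    """

    ids: list[str]
    offsets: np.ndarray
    values: np.ndarray  # (n_rows, 2W + 1)
    labels: np.ndarray | None = None  # cluster labels in 1..k

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.offsets)

    def column_means(self) -> np.ndarray:
        """The metagene line: mean profile across rows."""
        return self.values.mean(axis=0)


def build_profile_matrix(
    eluate_track: CoverageTrack,
    ft_track: CoverageTrack,
    plus1_nucs: Sequence[NucleosomeRecord],
    half_width: int = 500,
) -> ProfileMatrix:
    """Per-base eluate-minus-FT profiles at ``dyad +/- half_width``.

    Rows whose window runs off the chromosome are dropped with a warning.
    """
    if eluate_track.lengths != ft_track.lengths:
        raise ValueError("eluate and FT tracks cover different genomes")
    offsets = np.arange(-half_width, half_width + 1)
    rows, ids = [], []
    for rec in plus1_nucs:
        lo = rec.dyad - half_width
        hi = rec.dyad + half_width + 1
        length = eluate_track.lengths[rec.chrom]
        if lo < 0 or hi > length:
            warnings.warn(f"dropping {rec.id}: profile window out of bounds")
            continue
        row = eluate_track[rec.chrom][lo:hi] - ft_track[rec.chrom][lo:hi]
        if rec.interval.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(rec.id)
    if not rows:
        raise ValueError("no usable rows: all windows out of bounds")
    return ProfileMatrix(ids=ids, offsets=offsets, values=np.vstack(rows))


def kmeans_plus1(
    matrix: ProfileMatrix, k: int = 3, seed: int = 0, n_init: int = 10
) -> tuple[ProfileMatrix, list[str]]:
    """Cluster +1 profiles with k-means and flag high-signal clusters.

    Standard Euclidean k-means with k-means++ initialization and a fixed
    seed. Clusters are ranked by mean row-sum; every cluster whose mean
    row-sum is >= the matrix-wide mean row-sum is labeled preferred, and the
    ids of its rows are returned. Deterministic for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if matrix.values.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    raw = km.fit_predict(matrix.values)
    row_sums = matrix.values.sum(axis=1)
    # an empty cluster (degenerate input) ranks last and is never preferred
    cluster_means = np.array(
        [row_sums[raw == c].mean() if (raw == c).any() else -np.inf for c in range(k)]
    )
    # relabel clusters 1..k in descending mean row-sum order
    rank = np.argsort(-cluster_means)
    relabel = np.empty(k, dtype=int)
    relabel[rank] = np.arange(1, k + 1)
    labels = relabel[raw]
    preferred_clusters = {
        int(relabel[c]) for c in range(k) if cluster_means[c] >= row_sums.mean()
    }
    preferred_ids = [
        i for i, lab in zip(matrix.ids, labels) if int(lab) in preferred_clusters
    ]
    out = dataclasses.replace(matrix, labels=labels)
    return out, preferred_ids


def overlap_enrichment(hits: int, n: int, baseline_p: float) -> ZTestResult:
    """Is the observed overlap rate ``hits/n`` above the ``baseline_p``
    expected for randomly selected sites? One-sample proportion Z-test,
    one-sided upper. ``result.mu`` is the baseline, ``result.sigma`` the SE."""
    return proportion_ztest(hits, n, baseline_p)
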