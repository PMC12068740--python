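"""End-to-end convenience drivers tying the stages together.

These run the whole analysis on a synthetic world — the same call sequence a
user would compose by hand from :mod:`swrseq.chip` and :mod:`swrseq.invitro` —
and return the intermediate tables so results can be scored against the
world's planted truth.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from . import chip, invitro
from .simulate import SyntheticWorld, sample_chip_fragments, sample_pulldown_fragments

__all__ = ["ChipResult", "InvitroResult", "run_chip_pipeline", "run_invitro_pipeline"]


@dataclasses.dataclass
class ChipResult:
    calls: pd.DataFrame
    islands: chip.IslandSet
    class_counts: dict[str, int]

    @property
    def called_ids(self) -> set[str]:
        return set(self.calls.index[self.calls["swr_dependent"]])

    def recovery(self, truth: set[str]) -> tuple[float, float]:
        """(sensitivity over truth sites, false-positive rate over non-truth)."""
        called = self.called_ids
        universe = set(self.calls.index)
        non_truth = universe - truth
        sens = len(called & truth) / len(truth) if truth else float("nan")
        fpr = len(called - truth) / len(non_truth) if non_truth else float("nan")
        return sens, fpr


@dataclasses.dataclass
class InvitroResult:
    enrichment: dict[float, pd.Series]  # time point -> consensus Z-enrichment
    replicate_r2: dict[float, float]
    preferred: dict[float, list[str]]
    unpreferred: dict[float, list[str]]
    persistent_preferred: set[str]


def run_chip_pipeline(
    world: SyntheticWorld,
    n_frags: int = 200_000,
    n_reps: int = 2,
    scale_factor: float = 1.0,
    threshold: float = 10.0,
    seed: int = 0,
) -> ChipResult:
    """Simulate WT/mutant ChIP replicates and call SWR-dependent sites.

    The mutant RPM track is multiplied by ``scale_factor`` (the chromatin-bound
    abundance anchor) before subtraction; the synthetic mutant channel is
    generated at the same abundance as WT background, so the neutral value
    here is 1.
    """
    lengths = world.genome.lengths
    lo, hi = world.params.frag_len_range
    wt_counts, mut_counts = [], []
    for rep in range(1, n_reps + 1):
        wt = sample_chip_fragments(world, "WT", rep, n_frags, seed=seed)
        mut = sample_chip_fragments(world, "mutant", rep, n_frags, seed=seed)
        wt = chip.filter_fragments_by_length(wt, lo, hi)
        mut = chip.filter_fragments_by_length(mut, lo, hi)
        wt_track = chip.coverage_rpm(wt, lengths)
        mut_track = chip.coverage_rpm(mut, lengths).scaled(scale_factor)
        wt_counts.append(chip.count_at_nucleosomes(wt_track, world.nucleosomes))
        mut_counts.append(chip.count_at_nucleosomes(mut_track, world.nucleosomes))
    calls = chip.call_swr_dependent(
        wt_counts, mut_counts, world.nucleosomes, threshold=threshold
    )
    called = calls.index[calls["swr_dependent"]]
    by_chrom: dict[str, list[int]] = {}
    for nid in called:
        rec = world.nucleosome(nid)
        by_chrom.setdefault(rec.chrom, []).append(rec.dyad)
    dyads = {c: sorted(v) for c, v in by_chrom.items()}
    islands = chip.call_islands(dyads)
    class_counts = chip.classify_positions(calls, world.nucleosomes)
    return ChipResult(calls=calls, islands=islands, class_counts=class_counts)


def run_invitro_pipeline(
    world: SyntheticWorld,
    time_points: tuple[float, ...] = (15.0, 30.0, 45.0),
    n_frags: int = 200_000,
    n_reps: int = 2,
    tail_frac: float = 0.03,
    seed: int = 0,
) -> InvitroResult:
    """Simulate pulldown time courses and classify preferred substrates."""
    lengths = world.genome.lengths
    lo, hi = world.params.invitro_frag_len_range
    enrichment, r2s, pref, unpref = {}, {}, {}, {}
    for t in time_points:
        reps = []
        for rep in range(1, n_reps + 1):
            eluate, ft = sample_pulldown_fragments(
                world, t, n_frags, seed=seed, replicate=rep
            )
            eluate = chip.filter_fragments_by_length(eluate, lo, hi)
            ft = chip.filter_fragments_by_length(ft, lo, hi)
            e_track = chip.coverage_rpm(eluate, lengths)
            f_track = chip.coverage_rpm(ft, lengths)
            reps.append(invitro.z_enrichment(e_track, f_track, world.nucleosomes))
        if n_reps >= 2:
            r2s[t] = invitro.replicate_r2(
                reps[0].to_numpy(), reps[1].to_numpy()
            )
        consensus = invitro.consensus_enrichment(reps)
        enrichment[t] = consensus
        p, u = invitro.rank_classify(consensus, world.nucleosomes, tail_frac=tail_frac)
        pref[t], unpref[t] = p, u
    persistent = invitro.persistence_filter(list(pref.values()), min_times=2)
    return InvitroResult(
        enrichment=enrichment,
        replicate_r2=r2s,
        preferred=pref,
        unpreferred=unpref,
        persistent_preferred=persistent,
    )
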