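"""Rank nucleosomes by in vitro Z-enrichment and classify preferred substrates.

Pulldown time courses (15/30/45 min, two replicates) are simulated with
eluate odds increasing in each nucleosome's A/T tract content; Z-enrichment
(eluate minus flow-through RPM coverage) is ranked and the 3% tails define
preferred / unpreferred substrate sets.
"""

from swrseq.invitro import overlap_enrichment
from swrseq.pipeline import run_invitro_pipeline
from swrseq.simulate import WorldParams, make_world

world = make_world(WorldParams(), seed=1)
result = run_invitro_pipeline(world, n_frags=100_000, seed=3)

for t in (15.0, 30.0, 45.0):
    print(f"replicate R^2 at {int(t):2d} min: {result.replicate_r2[t]:.2f}")

baseline = len(world.truth_preferred) / len(world.nucleosomes)
pref = result.preferred[15.0]
hits = len(set(pref) & world.truth_preferred)
res = overlap_enrichment(hits, len(pref), baseline)
print(f"\ntop-3% tail size:         {len(pref)}")
print(f"tract-planted among them: {hits} ({100 * hits / len(pref):.0f}%)")
print(f"chance expectation:       {100 * baseline:.0f}%")
print(f"proportion Z-test:        z = {res.statistic:.1f}, p = {res.p_value:.2e}")
print(f"preferred at >= 2 time points: {len(result.persistent_preferred)}")
# A large z means the in vitro ranking recovers the planted tract-rich
# substrates far better than randomly picked nucleosomes would.
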