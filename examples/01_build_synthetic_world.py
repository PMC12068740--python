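"""Build a synthetic chromatin world and inspect its planted truth.

The world is a random 2 x 200 kb genome with 1,000 positioned nucleosomes:
18% depend on the SWR remodeler for H2A.Z deposition and 3% carry a planted
dA10 tract at the nucleosomal DNA entry/exit region, making them preferred
in vitro substrates.
"""

from swrseq.simulate import WorldParams, make_world

world = make_world(WorldParams(), seed=1)

print(f"chromosomes:        {dict(world.genome.lengths)}")
print(f"nucleosomes:        {len(world.nucleosomes)}")
print(f"SWR-dependent:      {len(world.truth_swr_sites)}")
print(f"tract-planted:      {len(world.truth_preferred)}")

nid = sorted(world.truth_preferred)[0]
offset, base = world.tract_placements[nid][0]
core = world.nucleosome_sequence(nid)
print(f"\nexample preferred nucleosome {nid}:")
print(f"  planted {base}-run at dyad-relative offset {offset}")
print(f"  core sequence around it: ...{core[offset + 73 - 5 : offset + 73 + 15]}...")
print(f"  A/T tracts >= 5 bp in core: {world.tract_count(nid)}")

# The planted run sits on the left half of the nucleosome (offsets -41..-31),
# the placement at which poly(dA) stimulates the remodeler most strongly.
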