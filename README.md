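# swrseq

Analysis toolkit for mapping where the **SWR chromatin remodeler** deposits
the histone variant **H2A.Z** across a genome, and for quantifying the DNA
sequence features — above all **poly(dA:dT) homopolymer tracts** — that make a
nucleosome a preferred SWR substrate.

It is written for chromatin genomicists working with nucleosome-resolved
paired-end sequencing data: H2A.Z ChIP-seq from a wild-type strain and a
deposition-null mutant, and in vitro remodeling reactions read out as a
streptavidin pulldown partition (eluate vs. flow-through). The package ships a
first-class synthetic-data module, so every stage of the analysis can be
exercised end-to-end, with known ground truth, on a laptop and with no
external downloads.

## What it computes

**SWR-dependent H2A.Z calling** (`swrseq.chip`). Fragments are size-filtered
(120–170 bp), converted to per-base coverage in reads per million (RPM) with
full fragment extent and a repeat mask, and the mutant profile is rescaled by
a chromatin-bound abundance factor measured by in vivo crosslinking (VivosX):

    factor = mean over replicates of (f_AZ + f_ZZ)_mutant / (f_AZ + f_ZZ)_WT

Per nucleosome, the signal is the mean RPM over the 147-bp core
`[dyad − 73, dyad + 74)`. A site is called SWR-dependent when

    Δ_rep = WT_rep − factor · mutant_rep ≥ 10   for every replicate,

and its significance is a one-sided one-sample Z-test against the mutant
counts as an empirical noise model, `z = (x − μ̂)/σ̂`, `p = 1 − Φ(z)`.
Called sites are clustered into **H2A.Z islands**: maximal groups of sites in
which each member shares a 1,500-bp window with at least 5 other sites.

**In vitro substrate preference** (`swrseq.invitro`). Z-enrichment at a
nucleosome is eluate-minus-flow-through RPM coverage (fragments filtered to
140–154 bp to suppress linker effects). Nucleosomes are ranked by replicate-
mean Z-enrichment; the top and bottom 3% tails define preferred and
unpreferred substrates. Replicate agreement is Pearson R²; overlap of the
preferred set with any reference set is tested with a one-sample proportion
Z-test, `z = (p̂ − p₀) / SE`, `SE = √(p₀(1 − p₀)/n)`. Dyad-anchored
per-base profiles at +1 nucleosomes are clustered with k-means (k = 3) to
flag high-signal +1 classes.

**Sequence signatures** (`swrseq.motifs`). Dinucleotide frequency profiles of
dyad-centered windows (147 bp + 20 bp flanks) against a genome-wide baseline;
poly(dA:dT) tract statistics where a *dA5 site* is a maximal top-strand A-run
of length ≥ 5 counted once (likewise dT5, dA10, dT10); in-frame 21-bp tiling
of coding sequences, whose positional dinucleotide profiles expose the 3-bp
codon periodicity that depletes homopolymer tracts from gene bodies; and
codon usage tables.

## Worked example

`examples/` contains one narrative script per capability. The end-to-end
ChIP calling example:

```bash
$ python examples/02_call_h2az_sites.py
chromatin-bound scaling factor (mutant/WT): 0.529

called sites:        211 of 1000
sensitivity:         100.0% of planted SWR-dependent sites
false-positive rate: 3.8% of unplanted nucleosomes
position classes:    {'+1': 37, '-1': 47, '+2': 39, 'distal': 88, 'called': 211}
islands:             0
```

The scaling factor 0.529 is the chromatin-bound abundance ratio computed from
the example crosslinking fractions (WT: 12% ZZ + 57% AZ; mutant: 2.5% ZZ +
34% AZ). On the default synthetic world — 1,000 nucleosomes, 18% of them with
a planted deposition effect 10× the sampling noise — every planted site is
recovered and 3.8% of unplanted nucleosomes are false positives under the
Δ ≥ 10 rule. The in vitro example (`03_invitro_preference.py`) ranks
nucleosomes by Z-enrichment and finds the top-3% tail 20-fold enriched for
tract-planted substrates (proportion Z-test z ≈ 20); the sequence example
(`04_sequence_signatures.py`) shows those substrates carrying dA/dT tracts
that the rest of the genome lacks.

A thin CLI mirrors the library (`swrseq simulate | chip-call | islands |
invitro | motifs | stats`), reading and writing plain BED / FASTA / bedGraph
/ TSV.

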