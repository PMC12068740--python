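# Methods

This note documents the models, conventions and numerical choices behind
`swrseq`, and what the synthetic-data generator does and does not emulate.

## Coordinate and strand conventions

All interval I/O is 0-based half-open (BED). A nucleosome is a 147-bp
interval whose dyad is `start + 73`; dyads are serialized as single-base
intervals `[d, d+1)`. Fragment input is 3-column BED of already-paired
fragments — read alignment and pairing happen upstream and are out of scope.
"Top strand" always means the genomic plus strand: positioned-nucleosome maps
carry no orientation, and the palindromic dAdA/dTdT enrichment around the
dyad is only well-defined on a fixed strand. The single place gene
orientation enters is the +1-profile matrix, where minus-strand rows are
reversed so that downstream is always rightward.

## Differential ChIP model

The quantity of interest is deposition that disappears when the remodeler is
inactivated: the WT-minus-mutant difference of H2A.Z coverage. Because the
mutant strain retains less chromatin-bound H2A.Z overall, RPM normalization
alone would overstate the difference; the mutant track is therefore rescaled
by an externally measured abundance anchor — the chromatin-bound (ZZ + AZ)
fraction ratio from in vivo crosslinking, averaged over replicate pairs.
The anchor is a free input: the widely used value for this comparison is
0.558, while the rounded example fractions in `examples/02` give 0.529; the
function computes whatever the supplied band fractions imply and asserts
nothing about either constant.

Per-nucleosome signal is the **mean** per-base RPM over the 147-bp core
rather than a sum, so values are comparable across universes and robust to
partial masking at window edges. Calling uses two rules jointly:

* a fixed effect-size threshold, `Δ ≥ 10` RPM units in *every* replicate
  (the comparison is `≥`, and calls are monotone non-increasing in the
  threshold);
* a one-sided significance measure per replicate, from a Z-test of the WT
  count against the empirical mutant-count distribution (sample mean and
  sample sd with denominator n−1; population sd would change nothing
  material at genome scale but the sample convention is the stated one).

Only the upper tail is tested — depletion is not a biological hypothesis
here — and no multiple-testing correction is applied, matching the practice
of reporting raw per-site p-values for a threshold-defined call set.
Nucleosomes overlapping the repeat mask get missing counts and propagate as
uncalled.

### Islands

A called site belongs to an island iff some 1,500-bp window contains it
together with ≥ 5 other called sites (equivalently, indices `i ≤ j` with
`dyad_j − dyad_i ≤ 1499` covering ≥ 6 sites). Qualifying windows that share a
site merge into one island; the island interval spans the first to last
member dyad. The window criterion determines membership exactly (verified
against brute-force enumeration of all O(n²) windows in tests); the merge
rule is the minimal completion that yields disjoint islands.

## In vitro preference model

Z-enrichment is the eluate-minus-FT difference of mean per-base RPM over the
core, after the stringent 140–154 bp fragment filter that minimizes linker
contributions to selectivity. Replicates are combined by the mean before
ranking (the combination rule is otherwise underdetermined — per-replicate
scatter is reported but one classification per time point is produced).

Tail classification takes `m = round(0.03 · N)` from each end of a single
total order: values descending, ties broken by ascending genomic coordinate.
This makes the preferred/unpreferred sets deterministic, disjoint, size-
matched and invariant under any strictly monotone transform of the values.
The persistence filter keeps substrates preferred at ≥ 2 of the 3 time
points.

k-means on +1-anchored profiles uses standard Euclidean k-means with
k-means++ initialization, 10 restarts and a fixed seed; the profile window
defaults to dyad ± 500 bp. Clusters are relabeled 1..k by descending mean
row-sum, and every cluster whose mean row-sum is ≥ the matrix-wide mean
row-sum is flagged preferred (the boundary is inclusive, so a degenerate
all-identical matrix flags everything rather than nothing).

## Sequence statistics

Dinucleotide profiles report, per offset, the fraction of sequences whose
top-strand dinucleotide at that offset equals each of the 16 motifs; windows
default to the 187-bp dyad ± (73 + 20) convention. Ambiguous bases are
excluded from the denominator at the affected offsets, so unambiguous rows
sum to exactly 1, and profiles of reverse-complement-closed sets obey the
mirror duality `freq(m, o) = freq(rc(m), −o − 1)`.

A *dA5 site* is a **maximal** A-run of length ≥ 5, counted once however long
it is (a dA10 run is one dA5 site, not six sliding matches); runs are broken
by any other character including N. Sliding-window counting would inflate
per-sequence means several-fold for tract-rich sequences and is not used.
Tract summaries report the fraction of sequences with ≥ 1 site and the mean
site count, for A-runs plus T-runs on the top strand.

Genic tiling cuts coding sequences into consecutive, non-overlapping 21-bp
tiles starting in frame (trailing remainders dropped) and averages positional
dinucleotide frequencies over tiles; codon-biased input produces the 3-bp
periodicity diagnostic of coding sequence, quantified in tests by the lag-3
autocorrelation of the mean-centered profile dominating lags 1–2.

## The synthetic world

The generator emulates the *structure* of the real data — not its biology:

* **Genome**: i.i.d. uniform ACGT over 2 chromosomes × 200 kb. Real yeast is
  ~62% AT with strong promoter tract structure; uniform background makes
  planted structure unambiguous and keeps accidental dA5 rates low (~24% of
  cores vs. 57% genome-wide in yeast).
* **Nucleosomes**: 1,000 cores on a fixed 200-bp grid, grouped into
  pseudo-genes of five with a −1/+1/+2 promoter trio and two gene-body
  nucleosomes, alternating gene strand. Real maps have variable spacing and
  fuzziness; neither matters to the operations under test.
* **SWR-dependent sites**: an 18% random subset — the genome-wide fraction of
  H2A.Z-enriched nucleosomes — receives a per-nucleosome ChIP sampling-weight
  increment `effect = 20` over a shared base weight 5, in the WT condition
  only. Per-draw Gaussian weight noise (`sd = 2`, truncated at 0 — a noted
  deviation from pure normality) plays the role of the mutant strain's noise
  model; its variance is a free parameter since no empirical value is
  published. With these defaults the planted effect is 10× the noise sd, and
  end-to-end recovery of ≥ 95% of planted sites with ≤ 5% false positives is
  a pinned-seed test property.
* **Preferred substrates**: a 3% random subset gets a planted top-strand dA10
  run starting between dyad-relative offsets −41 and −31 — the entry/exit
  placement with the strongest stimulatory effect on the remodeler — plus,
  with probability 0.5, the mirrored dT10 run on the right half. The
  pulldown sampler assigns each fragment to the eluate with probability
  `σ(α + β·tracts + γ·t)` (defaults α = −1, β = 1.5, γ = 0.01/min), so
  `β > 0` encodes tract preference and `β = 0` reduces to a fair split.
* **Genic sequences**: i.i.d. codons from a 61-dimensional weight vector
  (stops excluded), length 300 bp by default.

Fragments inherit the assay geometry: lengths discrete-uniform over 120–170
(ChIP) or 140–154 (in vitro), midpoints jittered ±20 bp around the dyad.
Not emulated: MNase and GC bias, PCR duplicates, linker-length variation,
inter-nucleosome correlation, real promoter sequence composition. Passing
tests therefore demonstrate the correctness and calibration of the
*computational* pipeline under its stated noise model, not performance on
real chromatin.

Problem sizes in tests and in `scripts/acceptance.py` (1,000 nucleosomes,
100,000 fragments per sample) were chosen so a full end-to-end run completes
in seconds while leaving the 3% tails (30 nucleosomes) statistically useful.

## Numerical details

* Normal tails via `scipy.stats.norm.sf`, accurate far beyond the 1e-9
  checked in tests; p-values are strictly decreasing in the statistic.
* The proportion Z-test uses the null variance `p₀(1−p₀)/n` (no continuity
  correction), cross-checked in tests against an independent implementation.
* RPM coverage is built by difference-array accumulation; the algebraic
  identity `total = 10⁶ × mean fragment length` is a test property.
* bedGraph output is run-length encoded and round-trips per-base vectors
  bit-exactly; an `emit_zeros` dialect flag controls whether zero runs are
  written (default: written).
* Degenerate inputs fail loudly: zero-variance noise models, empty
  nucleosome maps, out-of-bounds windows (dropped with a warning only in the
  profile-matrix builder, where partial universes are routine), unsorted
  island input, infeasible world packing.

## Known limitations

* The island merge rule beyond the window criterion is a design completion;
  alternative completions (e.g. non-merging overlapping windows) would split
  rather than join adjacent clusters.
* The abundance anchor is taken at face value from band fractions; no error
  propagation from densitometry into the call set is attempted.
* Tail sizes use `round(frac × N)`; published tail sizes may differ by a few
  sites when the ranked universe differs slightly from the nominal one, so
  published tail sizes should be treated as data, not derived constants.
* k-means labels depend on the seed only through ties and near-degenerate
  geometry, but determinism is guaranteed only for a fixed seed and restart
  count.
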