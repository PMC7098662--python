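# Methods

## The detection problem

A culture synchronized by an S-phase arrest and released traverses one cell
cycle while sampled at regular intervals; transcripts whose abundance tracks
a cell-cycle phase oscillate roughly once over the series, with amplitudes
that fade as cells drift out of phase with each other. The package detects
such genes from tpm matrices (genes × time points, two replicates),
classifies them into temporal waves, and places them in an evolutionary and
cross-species context.

## Rank tests and their null

Both tests reduce a series *x₁…xₙ* to its pairwise order signs
s᎐ᵢⱼ = sign(xⱼ − xᵢ) and score linear contrasts of them:

* **Cosine-correlation (JTK-style) statistic.** For each reference waveform
  rᵏ = cos(2π(t − l)/P) on the grid of periods *P* (sample units) and lags
  *l*, S = Σᵢ<ⱼ sign(rᵏⱼ − rᵏᵢ)·sᵢⱼ, i.e. the numerator of Kendall's τ-b
  against the discretized cosine. Reported τ uses the standard tie
  corrections for both variables.
* **Circular umbrella (RAIN-style) statistic.** For a candidate peak phase
  *k* and trough phase *m*, the contrast awards +1 to concordant rises
  along the circular arc *m→k* and to concordant falls along *k→m*, −1 to
  discordances, 0 to ties and to pairs spanning the peak. Trough offsets
  range over P/4…3P/4, so asymmetric rise/fall shapes — which a cosine
  correlate under-scores — are covered.

Because each statistic is a fixed linear form in the pair signs, the
permutation null of the whole grid is computed once and shared by every
gene whose series has no ties: all n! permutations when n ≤ 7 (exact mode),
otherwise 20 000 seeded random permutations. Tied series (e.g. clipped
zeros) get a dedicated null by permuting their own values; constant series
are flagged degenerate with p = 1. A normal approximation using the exact
permutation variance of each contrast (second moments of pair signs:
E[s²] = 1, shared-index pairs ±1/3) is available as a fast mode.

**Multiplicity over the grid.** The default combination is the permutation
minP adjustment: the observed minimum per-waveform tail fraction is
referred to the permutation distribution of that minimum, computed from the
same shared null. This is calibrated under the null — on i.i.d. noise both
tests reject at ~4–5% at α = 0.05 — whereas Bonferroni across the grid
(also available) rejects at only 1–2% because the waveform hypotheses are
strongly correlated. Smallest reportable p is 1/(M+1) with M permutations.

## Ranking and selection

Within each dataset the per-test p-values are Benjamini–Hochberg adjusted
and genes are ranked on the adjusted values (ties broken by raw p, then
gene id — deterministic by construction); the final score is the sum of the
two ranks. Selection requires a combined rank within the loose cutoff
(default 2000) in *each* replicate, and keeps the strict-cutoff best
(default 800) by the combined rank of the replicate-averaged dataset;
manual includes are added afterwards, excludes removed. The average dataset
is the element-wise mean of tpm (before normalization), filtered and tested
independently; the ranking universe is the intersection of the three
filtered gene sets. Expression filtering keeps genes with mean tpm
strictly above the threshold (default 1). Normalization is per-gene
z-scoring with the population SD (ddof = 0); any consistent convention
yields identical ranks and distances up to scale.

## Clustering and phase labels

Selected genes, z-scored on the averaged dataset, are grouped by
agglomerative clustering on Euclidean distances cut at exactly k groups
(default k = 5; linkage configurable among complete/average/ward/single,
default complete — the underlying recipe does not pin the linkage down) or
by seeded k-means with 10 restarts. Clusters are re-indexed by the peak
time of their mean profile and labeled with the phase window containing
that peak (defaults: G1/S 2–3.5 h, S 3.5–5.75 h, G2/M 6.5–7.25 h, M
9.5–11 h, G1 beyond 11 h wrapping to the start; peaks in the gaps get
"unassigned" with a warning). Agreement between two clusterings is
|intersection| / min(cluster sizes), per pair of clusters.

## Gene ages

Under Dollo parsimony (one gain, any losses) the most parsimonious origin
of a family is the MRCA of the species that have it; the package computes
this directly and the test suite verifies it against a brute-force
minimal-loss enumeration over all single-gain placements. Orthogroups
without a focal-species member are skipped; focal genes in no orthogroup
default to the youngest age class (0). Age classes are supplied as a node
label → integer map (the six-class scheme 0 species-specific … 5
Paneukaryotic is the default labeling). Cluster × age enrichment uses
two-sided Fisher tests on (in-cluster vs not) × (this age vs other), with
one Bonferroni family over all cells tested in a run and direction reported
from the enrichment ratio.

## Term enrichment

Annotations are propagated to all ancestors before testing (true-path
rule). Term-for-term mode is the one-sided hypergeometric test. The
parent-child-union mode restricts both study and population to genes
annotated to the union of a term's parents, so terms adding no genes beyond
their parents can never be called enriched; root terms are not tested, and
the Bonferroni family counts only tested terms. The recommended population
for cluster enrichment is the whole periodic program, making the question
"what distinguishes this wave from the rest of the periodic genes".

## Cross-species overlap

For a species pair, C = |orthogroups in common|, p1 and p2 = each species'
periodic orthogroups within C ("periodic" = at least one periodic member
gene), shared = periodic in both. The chance expectation is
A_exp = p1·p2/C, and the test refers the shared count to
Binomial(C, (p1/C)(p2/C)) — the unique binomial over the common universe
with that mean — one-sided for enrichment. A Fisher/hypergeometric variant
on the same 2×2 is provided for sensitivity analysis, as the trial count of
the published test is not derivable from its description. When every
common orthogroup is periodic in both species the plug-in success
probability is 1 and the test degenerates to p = 1: a fully saturated
universe carries no evidence of excess sharing over its own expectation.
The same statistic applies to one-to-one ortholog pair lists at gene level.
Genes mapping to no orthogroup are counted and logged, and excluded from
orthogroup-level analysis.

## Synthetic data

`generate_timecourse` draws, per gene,
x(t) = b + A·cos(2π(t − φ)/P)·e^(−λ(t−t₀)) + ε, clipped at zero: baseline
b log-uniform on 5–50 tpm, amplitude A uniform on 2–4 tpm for the periodic
fraction (zero otherwise), phase uniform, period 11 h, damping λ = 0.05/h,
ε ~ N(0, 1 tpm) i.i.d. per replicate with the deterministic part shared
between replicates. Defaults mirror the synchronized-culture design (16
samples every 0.75 h from 2 h post release, two replicates, ~10% periodic);
the damping rate is a free parameter — the real desynchronization rate is
not quantified anywhere — chosen so the last-cycle amplitude is roughly
halved. A configurable fraction (5%) of non-periodic genes carries a linear
drift to exercise specificity against monotone trends. The generator
emulates amplitude decay, additive noise and non-negativity, but not
count-based sampling noise, correlated gene modules, or redistribution of
the tpm simplex — so passing recovery tests demonstrate correctness of the
statistics on the assumed signal shape, not performance guarantees on any
real library-size regime.

`generate_orthogroup_universe` draws presence and per-species periodic
labels independently per orthogroup (the overlap test's null), optionally
forcing a planted fraction to be present and periodic everywhere.
`generate_family_history` gains a family at a chosen node and loses it
with fixed probability per branch below, never on the path to the focal
leaf, recording the true origin.

## Numerical choices and problem sizes

Permutation seeds derive from a single parameter seed; identical seeds give
bit-identical outputs. Recovery checks in the tests and the acceptance
script use 2000-gene universes with 10% planted oscillators at
amplitude/noise ≈ 3 (a few seconds per run with the shared null), 1000-gene
noise panels for calibration, 200 random 8-leaf trees for the Dollo oracle,
and 50 universes of 5000 orthogroups for overlap-null calibration; small
exact checks (n! permutation nulls, all 2×2 tables with n ≤ 40) run
exhaustively. The dual cutoffs scale with the universe (top 25% loose, top
10% strict in the synthetic runs, matching the 2000/800-of-8000 proportions
of the default settings).

## Known limitations

* The tests assume equally spaced samples; missing time points are not
  handled.
* Period grids are in sample units; non-integer periods are discretized by
  the cosine reference, not interpolated.
* No de-trending: a strong monotone drift inflates the umbrella statistic
  with peak at the boundary (mitigated, not removed, by the trough-offset
  bounds).
* Dollo ages are only as good as the orthogroup table and tree supplied;
  horizontal transfer or annotation gaps masquerade as young ages.
* The binomial overlap null conditions on estimated p1/C and p2/C; at very
  small C the plug-in is noticeably discrete and conservative.
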