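# cycletx

Detection and comparative analysis of **cell-cycle periodic transcription**
in synchronized bulk time courses, built around the analysis design used for
the filasterean amoeba *Capsaspora owczarzaki*: two rank-based periodicity
tests combined by rank sums with replicate-consistency cutoffs, clustering
of periodic genes into temporal waves, Dollo-parsimony gene ages, term
over-representation (including a parent-conditioned mode), and cross-species
overlap of periodic orthogroups against an explicit binomial null. A
synthetic-data module generates all inputs with known ground truth, so the
whole pipeline is testable end to end.

## Who this is for

Anyone analyzing synchronized-culture expression time courses (16-ish
samples, a couple of replicates, partial loss of synchrony) who wants a
reproducible, oracle-tested implementation of the rank-based detection
recipe and of the downstream evolutionary comparisons — without wiring
together several R packages and external binaries.

## The statistics

**Periodicity tests.** For gene *g* with expression series *x* over *n*
time points:

* *JTK-style*: Kendall's rank correlation τ between *x* and discretized
  cosine reference waveforms cos(2π(t−l)/P) over a grid of periods *P* (in
  sample units; default 14–16 samples ≙ 10.5–12 h at 0.75 h spacing) and all
  integer phase lags *l*.
* *RAIN-style (umbrella)*: a Jonckheere–Terpstra-type statistic counting
  concordant rises from a trough phase to a candidate peak phase and
  concordant falls back, taken circularly within one period and evaluated
  over all peak phases and asymmetric rise/fall splits.

Both statistics are linear in the pairwise order signs of *x*, so one
permutation null (exact n! enumeration for n ≤ 7, otherwise 2·10⁴ seeded
permutations) is shared by every untied gene. Significance over the
waveform grid uses a permutation minP adjustment (calibrated under the
null), with plain Bonferroni available.

**Selection.** Per dataset, genes are ranked on Benjamini–Hochberg adjusted
p-values of each test and the two ranks are summed (`combined_rank`).
Periodic genes must rank ≤ 2000 in *both* replicates and within the top 800
of the replicate-averaged dataset (defaults; both cutoffs configurable),
with manual include/exclude lists applied last.

**Downstream.** Selected genes are z-scored and clustered (Euclidean
hierarchical or k-means, k = 5 by default) into waves labeled by the
cell-cycle phase at their peak. Gene ages come from Dollo parsimony — the
origin of an orthogroup is the MRCA of the species possessing it — and are
tested for enrichment per cluster (two-sided Fisher, Bonferroni). For two
species sharing *C* orthogroups with *p1* and *p2* periodic ones, the
expected chance overlap is *A*<sub>exp</sub> = *p1·p2/C*, and the observed
shared count is tested against Binomial(*C*, (*p1/C*)(*p2/C*)).

## Worked example

```python
from cycletx import (SimulationConfig, generate_timecourse, PeriodicityParams,
                     SelectionRule, detect_periodic_genes, hierarchical_clusters,
                     assign_phase_labels, zscore_normalize)
from cycletx.periodicity import ExpressionTimeCourse

cfg = SimulationConfig(n_genes=2000, periodic_fraction=0.1, seed=1)
replicates, truth = generate_timecourse(cfg)

selected, tables, average = detect_periodic_genes(
    replicates, PeriodicityParams(seed=1),
    SelectionRule(loose_cutoff=500, strict_cutoff=200))

truth_map = dict(zip(truth.gene_id, truth.is_periodic))
tp = sum(truth_map[g] for g in selected)
print(f"selected {len(selected)} genes; {tp} are truly periodic "
      f"(sensitivity {tp / truth.is_periodic.sum():.2f})")

keep = [g in set(selected) for g in average.gene_ids]
profiles = zscore_normalize(ExpressionTimeCourse(
    gene_ids=[g for g, k in zip(average.gene_ids, keep) if k],
    times=average.times, values=average.values[keep]))
waves = assign_phase_labels(hierarchical_clusters(profiles, k=5))
for c in range(1, 6):
    print(f"cluster {c}: {len(waves.members(c)):3d} genes, "
          f"peak {waves.peak_times[c]:5.2f} h, phase {waves.phase_labels[c]}")
```

Output:

```
selected 184 genes; 183 are truly periodic (sensitivity 0.92)
cluster 1:  24 genes, peak  2.00 h, phase G1/S
cluster 2:  27 genes, peak  2.75 h, phase G1/S
cluster 3:  46 genes, peak  5.00 h, phase S
cluster 4:  44 genes, peak  6.50 h, phase G2/M
cluster 5:  43 genes, peak 10.25 h, phase M
```

The 2000-gene universe holds 200 planted oscillators; the dual-cutoff rule
(top 25% in each replicate, then the 200 best of the average) recovers 92%
of them with a single false positive, and the five waves tile the sampled
cycle from release (2 h) through mitosis (~10 h).

The same workflow is available from the shell:

```bash
cycletx simulate --n-genes 2000 --seed 1 --out-dir sim
cycletx detect --rep1 sim/rep1.tsv --rep2 sim/rep2.tsv \
    --loose 500 --strict 200 --seed 1 --out-dir detection
cycletx run-all --rep1 sim/rep1.tsv --rep2 sim/rep2.tsv --k 5 ...
```

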