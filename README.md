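# cryptohyb

Population-genetic analysis of two sympatric cryptic species, built around
the question: do two genetically divergent lineages sharing the same roosts
actually interbreed?  The package implements the full nuclear + mitochondrial
+ phenotypic workflow used to answer it for a two-species bat system:

* **Bayesian admixture clustering** of multilocus microsatellite genotypes
  (Gibbs sampler under the admixture model with correlated allele
  frequencies), multi-run consensus with label alignment, and **Evanno ΔK**
  model selection;
* **simulation-calibrated hybrid detection**: simulate parental, F1, F2 and
  backcross genotypes from reference parents, calibrate per-cluster
  thresholds TP1/TP2 as the lowest simulated-parent *q*, classify
  individuals by mean *q* (conservative) or the 90% credibility lower bound
  (relaxed), and measure parental misclassification over replicated
  simulations;
* **Weir–Cockerham F-statistics** (θ with bootstrap-over-loci CI, per-locus
  F_IS), locus quality screens (null alleles via the Chakraborty estimator
  with an exact binomial test; Hardy–Weinberg and linkage-disequilibrium
  permutation tests with Bonferroni correction), pairwise-population exact
  G-tests, and an F_ST-based **sex-biased dispersal** randomization test;
* **mitochondrial barcoding**: raw *p*-distances, single-linkage haplogroup
  partitioning, and cyto-nuclear discordance tables quantifying asymmetric
  mtDNA introgression;
* **nested two-way ANOVA** of phenotypes (forearm length, echolocation peak
  frequency) with sex-by-group interaction tests and post-hoc *t*-tests;
* a **synthetic-data generator** that emulates the whole study system
  (two clusters at multilocus θ≈0.14, 15 loci with 2–17 alleles, 1.3%
  missing data, asymmetric mtDNA introgression at p=0.158, group-specific
  sexual dimorphism) with full ground truth for recovery testing.

## The model at the core

Each individual *i* carries ancestry proportions **q**_i ~ Dirichlet(α,…,α)
over K clusters; each allele copy at locus *l* originates from cluster *k*
with probability q_ik and is drawn from that cluster's frequencies
**p**_kl.  Cluster frequencies follow the correlated-frequencies (F-model)
prior, **p**_kl ~ Dirichlet(**p**_Al·(1−F_k)/F_k), around an ancestral
vector **p**_Al with per-cluster drift F_k.  Differentiation is summarised
by Weir & Cockerham's θ = Σa / Σ(a+b+c) over the per-allele variance
components, and hybrid status is decided against thresholds calibrated on
simulated pure parents.

## Worked example

Run the numbered analysis scripts in order (each prints what it found and
writes tables under `results/`):

```bash
python analysis/01_simulate_dataset.py
python analysis/02_cluster_evanno.py
python analysis/03_screen_loci.py
python analysis/04_hybrid_detection.py     # add --replicates 30 for the misclassification study
python analysis/05_popgen_stats.py
python analysis/06_mtdna_discordance.py
python analysis/07_phenotypes.py
```

Output of an actual run (seed 11):

```
== 02_cluster_evanno ==
   Evanno selects K = 2 (deltaK = 58656 at K=2)
   cluster sizes: 325 A / 423 B
== 05_popgen_stats ==
   multilocus theta = 0.138 [0.088-0.183]95% over 13 loci
   species A, M-dispersal test: theta_F - theta_M = +0.0005, p = 0.437
== 06_mtdna_discordance ==
   2 haplogroups; within means B: 0.0084, A: 0.0017; between 0.0608
   discordance {'A->B': 0.21052631578947367, 'B->A': 0.0} (asymmetric: True)
== 07_phenotypes ==
   forearm: means A 64.33 / B 62.06; group effect F = 266.92 (df 1,438), p = 3.4e-47
   forearm: ... post-hoc A: t = -1.72, p = 0.087 (M > F); B: t = 3.11, p = 0.0021 (F > M)
```

Reading this: the sampler recovers the two generated species exactly
(325/423); multilocus θ=0.138 matches the design differentiation and the
bootstrap CI conveys the 13-locus sampling spread; the barcode splits into
two haplogroups an order of magnitude more divergent between than within,
with discordant individuals only in the A→B direction (asymmetric
introgression); and forearm length differs between species with sexual
dimorphism detectable only in species B — all properties the generator
planted.  Two loci were dropped by the null-allele screen (raw p<0.05 over
30 tests makes occasional false flags expected); downstream statistics use
the retained 13.

The same workflow runs on real data: `cryptohyb.pipeline.run_pipeline`
accepts genotype CSV / two-row text, FASTA and metadata CSV paths in place
of the simulation config, and `PipelineConfig.from_yaml` loads everything
from one file.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the entire pipeline from scratch at desk scale (simulation →
clustering over K=1..4 with Evanno selection → locus screens and
re-clustering → hybrid threshold calibration and classification → θ →
discordance → phenotype ANOVAs), prints the consolidated report, writes it
to `results/pipeline_report.json`, and writes the (empty) target map to
`--out`.  It takes a couple of minutes on one CPU.

## Layout

```
src/cryptohyb/      genodata, synthetic_data, admixture, hybrid_detection,
                    popgen_stats, mtdna, phenotypes, pipeline
analysis/           numbered narrative drivers over the library
tests/              pytest suite (unit, property and acceptance tests)
docs/methods.md     models, assumptions, numerical choices, limitations
```
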