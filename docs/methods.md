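# Methods

## Admixture model and sampler

The clustering model is the standard admixture model with correlated allele
frequencies.  Observed data are diploid co-dominant genotypes X_il = (x_il1,
x_il2) for n individuals at L loci; missing genotypes contribute no
likelihood terms.  Latent structure: per-copy origins z_ilc ∈ {1..K},
ancestries q_i ~ Dirichlet(α,…,α), cluster frequencies p_kl ~
Dirichlet(p_Al·(1−F_k)/F_k) with ancestral frequencies p_Al ~ Dirichlet(1)
and per-cluster drift F_k.

One Gibbs sweep updates, in order: (1) z_ilc ~ Categorical(∝ q_ik
p_kl(x_ilc)); (2) q_i ~ Dirichlet(α + origin counts); (3) p_kl ~
Dirichlet(p_Al(1−F_k)/F_k + assigned allele counts) — the F-model prior is
conjugate given z; (4) F_k by random-walk Metropolis on the Dirichlet
compound likelihood of p_k given (p_A, F_k); (5) p_Al by a pairwise
mass-transfer Metropolis move (two alleles, Normal(0, 0.05) transfer),
vectorized over loci; (6) α by random-walk Metropolis with a uniform(0,
α_max=10) prior.  The data log-likelihood Σ log Σ_k q_ik p_kl(x) is traced;
model evidence per run is estimated as lnPD = mean(lnL) − var(lnL)/2, the
cited clustering program's estimator.  90% credibility intervals are the
5th–95th percentile band of retained q samples.

Defaults mirror the study settings (burn-in 300,000, length 1,000,000,
thin 100; F prior Gamma with mean 0.01, sd 0.05; α proposal sd 0.025).
`desk_config()` provides the reduced preset (5,000 / 20,000 / 10).  Tests
and the acceptance layer run shorter chains still (~1,000–2,000 burn-in,
3,000–6,000 length) and pass `alpha_prop_sd=0.2`: the α random walk at sd
0.025 is tuned for million-sweep chains and cannot traverse from its
initial value within a short chain, which inflates q credibility intervals;
a proposal scale changes mixing speed only, never the stationary
distribution.  At the default differentiation (θ≈0.14, 15 loci) the
posterior is so concentrated that label recovery is 100% at these lengths.

Multi-run consensus: runs are aligned to the first run by the label
permutation minimizing summed |q| distance (exact search for K ≤ 6, greedy
above), then q and the CI bounds are averaged element-wise.  Evanno's
ΔK(K) = |mean lnPD(K+1) − 2·mean lnPD(K) + mean lnPD(K−1)| / sd(lnPD(K)) is
computed for interior K of a consecutive ladder with ≥ 2 runs per K; zero
standard deviation leaves ΔK undefined at that K rather than infinite.
Individuals with no amplified loci are retained with a warning (their q is
the prior posterior); dropping them would misalign ids across modules.

## Hybrid detection

Reference parents are the 80 individuals with the highest consensus q per
cluster (ties by id).  Simulants are generated at the gamete level from the
pools' empirical allele frequencies: a pool gamete draws one allele per
locus from its pool; an F1 gamete draws per locus from pool A or B with
probability 1/2 (one crossover-free meiosis, loci unlinked); parental = two
pool gametes, F1 = one gamete from each pool, F2 = two F1 gametes, BC_X =
F1 gamete × pool-X gamete.  Simulants carry no missing data.

Thresholds: simulants are pooled and clustered afresh at K=2 with no
prior information (not projected onto fixed parental frequencies); TP_k is
the lowest q of a simulated parent in cluster k.  Classification of a real
individual with majority cluster k: conservative — parent of k iff mean
q_k ≥ TP_k; relaxed — the same rule applied to the 90% CI lower bound in
cluster k (the majority cluster only, reading the source procedure's
singular "credibility interval").  The relaxed hybrid set therefore always
contains the conservative set.  The misclassification study re-simulates
the {300 parental A, 300 parental B, 10 F1, 15 BC_A, 15 BC_B} mix, clusters
each replicate once, classifies against the *supplied* thresholds, and
counts parental simulants flagged hybrid.

## Estimators and tests

* Weir–Cockerham (1984) components a, b, c per allele per locus; multilocus
  θ = Σa / Σ(a+b+c); 95% CI by percentile bootstrap over loci (1,000
  resamples, seeded).  Per-group F_IS uses the single-sample (r = 1) limit
  of the same components.
* Diversity: Na = distinct non-missing alleles; Ho = heterozygote fraction
  among amplified individuals; He = Nei's unbiased 2n/(2n−1)(1−Σp²).
  Rarefied allelic richness (hypergeometric formula) is available but Na is
  the reported quantity.
* HWE: statistic = single-sample Weir–Cockerham f; null = random re-pairing
  of the group's alleles at the locus (the randomization of the cited
  F-statistics program), two-sided by default with a one-sided deficit
  option; Bonferroni across locus × group tests.  Since allele frequencies
  are permutation-invariant, f under the null depends only on the total
  heterozygote count, which the implementation exploits for vectorization.
* LD: G log-likelihood on the two-locus genotype table, summed over groups;
  null permutes one locus's genotypes within groups.
* Null alleles: Chakraborty estimator r = (He−Ho)/(He+Ho) by default
  (Brookfield-1 available); significance by a one-sided exact binomial test
  of the observed homozygote count against its Hardy–Weinberg expectation.
  Loci failing this screen (raw p < 0.05, either group) or the Bonferroni
  HWE screen are excluded and clustering is re-run on the retained set; an
  abort triggers if fewer than 5 loci would remain.
* Pairwise differentiation: per-pair θ plus a G test on allele counts with
  the null built by permuting multilocus genotypes between the two groups.
* Sex-biased dispersal: statistic θ_F − θ_M over sites; sex labels permuted
  within sites; unilateral p for the hypothesized dispersing sex (dispersal
  homogenizes, so the dispersing sex is expected to show lower θ).
* All permutation p-values use (b+1)/(m+1).
* Raw mtDNA distances: proportion of differing sites among sites where both
  sequences have A/C/G/T (all other characters, including ambiguity codes,
  are deleted pairwise).  Haplogroups: single-linkage connected components
  at distance ≤ 0.02, a cutoff an order of magnitude above within-group and
  below between-group divergence.  Tree building is deliberately out of
  scope: the claims carried here (non-overlapping haplogroups, divergence
  summaries, discordance counts) depend only on distances.
* Phenotypes: OLS fits of the nested models Group, Sex, Sex+Group,
  Sex*Group.  The group effect corrected for sex is the 1-df incremental SS
  of Group over Sex against the full-model mean square (this matches the
  source's printed df); "any sex effect" compares Sex*Group to Group (2 df)
  and the interaction compares Sex*Group to Sex+Group (1 df).  Post-hoc
  equal-variance t-tests compare sexes within each group.  Outlier
  screening replaces a visual judgement with a reproducible rule — values
  below Q1 − 3·IQR within group are dropped and logged; the source texts
  disagree on whether 4 or 5 points were removed, so the rule is
  deliberately count-free.

## Synthetic-data generator

The generator states the study world explicitly: 325 + 423 individuals in
two species; 15 loci whose allele counts are uniform on 2–17; ancestral
frequencies Dirichlet(1); species frequencies Balding–Nichols
Dirichlet(p·(1−F)/F) at drift F = 0.139 per species (realized multilocus θ
tracks F; `calibrate_drift` refines F by simulation and lands within
Monte-Carlo error of 0.139, so the nominal value is kept); genotypes are
Hardy–Weinberg draws; 1.3% of genotypes missing.  Optional hybrid classes
use the same gamete semantics as the detector.  The barcode alignment has
two consensus sequences differing at round(0.057·500) sites; individual
sequences mutate per site at within-diversity/2 (uniform sites, no rate
heterogeneity — sufficient for raw distances); 38 + 42 pure individuals are
sequenced; each species-A individual carries the B haplogroup with
probability 0.158 (6/38 in the source), never the reverse.  Sex composition
follows the field totals per species; phenotype means are the reported
group means with dimorphism gaps back-computed from the reported post-hoc t
statistics, and standard deviations from the reported 95% CIs
(sd = half-width·√n/1.96) — forearm ≈ 1.41 mm both species, call frequency
0.89 / 0.61 kHz.  Sites are sampling labels with no spatial genetic
structure (the study found essentially none); planted locus defects
(non-amplifying alleles; inbreeding-style heterozygote deficit) are
available for screen testing and default to zero.

What a green recovery test establishes: the estimators see the structure
the generator planted (differentiation, haplogroups, introgression
direction, dimorphism pattern).  What it does not: realism of microsatellite
mutation (no stepwise mutation, no allele-size homoplasy), linkage,
within-species spatial structure, or real allele-frequency spectra —
between long-diverged species many real alleles are private to one species,
which the F-model (shared allele sets with perturbed frequencies) does not
reproduce.

## Known limitations

* The parental misclassification study reproduces the conservative null
  result (4 flags in 18,000 parental simulants ≈ 0) but not an exact null
  for the relaxed rule: in this synthetic world ~0.5–1% of parental
  simulants have a 90% CI lower bound below the calibrated thresholds.
  This is genuine posterior width (stable across chain lengths, drift
  priors and proposal scales), and plausibly reflects the F-model's less
  diagnostic allele-frequency spectra relative to real cryptic species
  (see above) — the corresponding acceptance test is left failing rather
  than weakened.
* lnPD is a plug-in evidence estimate; ΔK comparisons are only as good as
  the spread of runs per K (two runs is the floor).
* The desk-scale chain lengths are validated only for strongly separated
  clusters; weakly structured data need the full-scale settings.
* Half-missing genotypes (one allele of a pair) are rejected as invalid
  records rather than treated as haploid observations.
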