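# Methods

## The analysis in one paragraph

Two conspecific populations are compared: NB, treated as the closest
available representation of their shared ancestral state, and B, which
recently collapsed to a diploid effective size in the tens.  Diversity is
summarised per *genomic unit* — one contiguous interval of a single feature
class — as per-site π, Watterson's θ_W and the SFS skew S = 1 − π/θ_W,
pooled with informative-site weights across features, chromosomal regions
and chromosomes.  Feature-wise comparisons between the populations use the
relative difference δ = (B − NB)/(B + NB) in equal-information windows on
concatenated units, and window classes defined from δ_θW are contrasted on
genomic covariates.  A Wright–Fisher simulator generates all inputs.

## Simulation model

**Ancestral equilibrium.**  Each site is independently polymorphic with
probability θ·Σw_i (θ = 4·Ne·μ), and a polymorphic site's derived-allele
frequency is drawn from a discrete SFS over `2·Ne` frequency classes with
weights `w_i = (1/i)·exp(−4·Ne·s·i/(2·Ne))`: the neutral 1/i spectrum,
exponentially reweighted for deleterious additive variants so that strongly
constrained classes are singleton-rich.  This closed-form equilibrium
replaces a burn-in forward simulation; it is exact for neutral infinite
sites and a standard approximation under selection, and it is the package's
stand-in for an unknown real ancestral spectrum, not an estimate of one.

**Bottleneck.**  The B population starts from the *same* ancestral
frequencies and drifts `g_B` generations at diploid size `Ne_B`: per
generation, deterministic additive selection `p' = p(1−s)/(1−ps)`, symmetric
mutation `p'' = p'(1−μ) + (1−p')μ`, then binomial sampling of `2·Ne_B`
gametes.  With the default `Ne_B = 10`, selection at `s < 1/(2·Ne_B) = 0.05`
is effectively neutral during the bottleneck — the nearly-neutral window
the analysis is designed to expose.

**The X.**  Contigs flagged X use 3/4 of the autosomal effective size at
equilibrium and during drift (male hemizygosity), and sampled males carry a
single haploid X call.  Downstream, θ_W on the X uses the per-site haploid
sample size, which equals 2F + M when all individuals are called.

**Sampling.**  Individuals are formed by random union of gametes
(binomial sampling from population frequencies); genotypes go missing
i.i.d. per site per individual at `missing_rate`.

**Defaults** (the study conditions; all configurable):

| parameter | default | rationale |
|---|---|---|
| Ne_anc | 2000 diploids | large enough for a singleton-rich constrained SFS at desk scale |
| Ne_B, g_B | 10, 40 | bottlenecked-population size in the tens, tens of generations |
| samples | 12 + 12 diploids, half female | panel sizes of the motivating study design |
| μ per site | 2.2–3.0 × 10⁻⁶ by class | θ = 4·Ne·μ ≈ 0.02, so 1-kb windows hold tens of variants; promoters/UTRs slightly elevated so divergence/GC covariates correlate with mutation rate |
| s by class | 0 (intergenic) … 0.02 (CDS), 0.04 (UCNE) | constraint ladder; UCNE inside the 0.025–0.05 nearly-neutral window of Ne = 10 |
| missing_rate | 0.10 | creates a realistic informative-site structure |
| region μ multiplier | 1.4 subtelomeric, 0.7 pericentromeric | encodes the higher/lower diversity of chromosome ends/centromere surroundings |
| genome | 8 contigs × 50 kb | desk-scale; tests use 4–8 contigs of 12–30 kb |

Per-gene constraint heterogeneity (lognormal multiplier on gene-body s,
σ = 0.4) makes genes differ in realised constraint; the RVIS covariate is
emitted anticorrelated with each gene's realised s, divergence is Bernoulli
per site with probability ∝ μ, GC probability is an affine function of μ,
and recombination is a windowed track elevated in subtelomeric and
suppressed in pericentromeric regions.

**What the generator does not emulate:** linkage and recombination within
the simulator (sites are exchangeable; linked selection appears only
through per-class s and μ), dominance, gene conversion, genotyping error
from read data, and reference bias.  Passing tests therefore demonstrate
the correctness and calibration of the estimators and tests on panels with
known structure — not robustness to the mapping/calling artefacts of real
resequencing data.

## Estimators and filters

"Informative site": at least half of the population's individuals have a
genotype and at least two haploid calls are present.  Sites with more than
two alleles are dropped on VCF read.  Units are kept when they retain
*more than* 50 informative sites covering at least 20% of their positions
(strict >50; ≥0.20).  Per-site estimators use the per-site haploid count,
making them missingness-aware and unbiased; invariant sites contribute
exactly 0 (unlike genotype-likelihood pipelines whose per-site values are
never exactly zero — see "count-based replacement" below).

Units get a region label when one region class covers ≥75% of their
length, else they are unassigned and excluded from regional summaries;
units spanning a chromosome boundary are excluded from chromosome-level
summaries.  Promoters are the 1000 bp upstream of each gene/lncRNA
(strand-aware, clipped); intergenic is the complement of all annotation
±1000 bp.  Promoters may overlap other features; overlaps are recorded, not
resolved, since the unit tables carry coordinates.

The PAR default (10 Mb at the start extreme of the X) matches a felid-scale
chromosome; simulated toy X chromosomes are far shorter, so pipeline demo
configs set `par_bp` proportionally.

## Windowed δ analysis

Windows are **1000 matched informative sites**, not 1000 genomic bp: both
populations are subsampled to the same number of individuals (seeded,
without replacement), only sites informative in both retained, and units of
one feature concatenated in genomic order.  Equal-information windows keep
the δ variance comparable across features of different unit lengths.

The zero-transform sets both δ_θW and δ_π to 0 where *θ_W in both
populations* falls below a "no diversity" threshold.  With `auto`, the
threshold is fitted as the valley of a smoothed log₁₀ histogram of window
θ_W between its two largest modes — the operationalisation of the
bimodality that genotype-likelihood window diversities show.  Two guards
make the fit safe on count-based input: a second mode must be non-negligible
(≥5% of the main mode) and clearly separated (valley below half the minor
mode), and a fitted threshold above 10⁻⁴ (≈ one variant per 1-kb window) is
rejected in favour of the 10⁻⁶ fallback, because a valley above the
one-variant floor separates genuinely different diversity levels (e.g.
feature classes), which must not be zeroed.  Count-based "empty" windows
sit at exactly 0 and are zeroed by any positive threshold.

Feature δ distributions are compared against intergenic windows with a
paired Wilcoxon signed-rank test (series truncated to the common window
count, in order; an unpaired Mann–Whitney mode is available since the
natural pairing unit is genuinely ambiguous), Bonferroni-corrected over the
comparisons performed.  Window-class contrasts (δ_θW > 0.1 gain windows vs
the rest within CDS/intron/intergenic; ND_NB-ND_B vs ND_NB-D_B among
windows without NB diversity) use Mann–Whitney with tie and continuity
corrected normal Z (exact null distribution when both groups ≤10 and
untied), effect size r = |Z|/√N, and Bonferroni within each contrast
family.

## Numerical and design choices

- Coordinates are 0-based half-open throughout (BED convention); VCF
  positions convert on read/write.  Emitted VCFs are *all-sites* so that
  informative-site bookkeeping survives the file round trip.
- Harmonic numbers come from a cumulative table indexed by per-site n.
- Bootstrap SDs use `n_iter` resamples with replacement of units (100) or
  windows (1000); CIs are percentile 95%.  All resampling, subsampling and
  simulation draws descend from one seed through named `SeedSequence`
  substreams, so any stage re-run in isolation reproduces its output.
- Regression p-values are unadjusted (descriptive heat-map use);
  chromosome-level regressions are unweighted OLS.
- X/A ratio uncertainty: sd = √(sd_A²/A² + sd_X²/X²)·(X/A).
- The group-level S is computed from pooled π and θ_W (not averaged
  per-unit S), with its bootstrap SD from jointly resampled units.
- `weighted_mean` drops NaN values together with their weights; a unit with
  θ_W = 0 has undefined S (NaN), which propagates as missing.

## The count-based replacement of genotype-likelihood estimation

The motivating analysis estimated per-site diversity from genotype
likelihoods (read-level uncertainty, nonzero values at invariant sites).
Here, with simulated called genotypes, count-based estimators target the
same population quantities and are exactly unbiased given the calls.  One
documented consequence: in a strongly constrained, singleton-rich class the
NB sample SFS sits at the singleton ceiling (S ≈ 1 − (2/n)·a_{n−1}, ~0.66
at n = 24), so a post-bottleneck sample drawn from a pool of ~2·Ne_B
chromosomes can never be *more* singleton-skewed, and the mean δ_θW of such
a class cannot exceed its mean δ_π — gains in variant density and in
pairwise diversity move together.  Likelihood-based window values, whose
low-diversity mode is a continuous noise floor rather than exact zeros,
behave differently in this corner.  The package's simulation experiments
(`driftscape.experiments`) assert the robust part of the signature — the
constrained class's mean δ_θW lies well above the neutral intergenic one
after a bottleneck — which holds in 100% of seeds at the default regime.

The null calibration experiment (B sampled from NB's generation) uses
neutral feature classes, 20 diploids per population and features with ≥10
windows: window bootstrap CIs are conditional on the sampled panels, so
panel-level noise (shared across windows, invisible to the bootstrap) must
stay subdominant, and sparse selected classes would add discrete-δ
artefacts that the likelihood world this procedure mimics does not have.
Measured coverage of 0 by the 95% CIs is 0.90–0.93 across independent seed
families.

## Known limitations

- Free recombination between sites and none within them; no linked
  selection, sweeps or background-selection gradients beyond the per-class
  s ladder.
- The equilibrium SFS under selection is an approximation (no exact
  diffusion solution, no dominance, no interference).
- Sample sizes exceeding 2·Ne_B effectively census the bottlenecked pool;
  frequencies below 1/(2·Ne_B) do not exist in B.
- The simulator's covariate tracks encode *designed* correlations (μ↔GC,
  μ↔divergence, s↔RVIS); regressions on them validate the pipeline's
  plumbing and power, not any empirical claim about real genomes.
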