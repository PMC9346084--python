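# Methods

This note documents the statistical models, the synthetic-data
generators, and the numerical and design choices behind `thermoadapt`.

## Survival models (`thermoadapt.survival`)

**Model.** Each rearing tube contributes `n_alive` of `n_total`
survivors, modelled as Binomial with a logit link.  Fixed effects are
treatment-coded experimental factors (references: population SFB84,
clutch 1, parental treatment control, early regime and test regime
T_SFB, microbiome LAB), so population coefficients are log odds ratios
against the ancestral population.  Two random intercepts are supported: a
*family* intercept `u_f ~ N(0, σ²_fam)` shared by tubes from one parental
couple, and an *observation-level* intercept `e_i ~ N(0, σ²_obs)` — the
standard device for extra-binomial overdispersion in binomial GLMMs.
The two thermal regimes are always analysed separately; they enter the
data as categorical labels only.

**Clutch coding.** Clutch is a 0/1 dummy (`clutch_dummy`, second clutch
= 1) and parental treatment is restricted to interaction terms with it.
Treatments were applied between the clutches, so this coding prevents the
model from estimating a (biologically impossible) treatment effect on
first-clutch offspring.

**Fitting.** The marginal likelihood integrates the random intercepts out
with Gauss–Hermite quadrature: 25 nodes per dimension, nested (family
outer, observation inner) when both terms are present.  Plain quadrature
is accurate here because tube sizes are small (n ≈ 10) and intercept SDs
are moderate (≲ 2 on the logit scale); the suite verifies agreement with
`lme4::glmer` at `nAGQ = 25` on the family model.  Optimization is
L-BFGS-B over (β, σ_fam, σ_obs) with σ ≥ 0, started from the plain
logistic MLE (damped Newton), with a Nelder-Mead polish; standard errors
come from the numerical Hessian at the optimum.  Non-convergence and
separation (|β| > 10) are flagged on the fit object, never silently
ignored.

**Inference.** Nested models are compared by likelihood-ratio tests
against the χ²(df) reference; tests concern fixed effects only, so no
boundary correction for variance components is applied.  Post hoc
pairwise comparisons use z statistics with the Tukey (studentized-range,
infinite df) family adjustment; for a two-level factor the adjusted p
equals the unadjusted two-sided p.

**Overdispersion rule.** The dispersion ratio is the sum of squared
Pearson residuals (conditional on family-intercept posterior modes) over
residual df.  The observation-level intercept is added when the ratio
exceeds **1.4**; the threshold is a package choice (the rule in the field
is "where necessary") and the ratio is always logged.

**Effect sizes.** Four "control" subsets feed the meta-analysis: first
clutches of the parental-acclimation experiment; unexposed
(control-treatment) second clutches; lab-microbiome tubes; and
juvenile-acclimation tubes whose early regime matched the test regime.
Per subset and regime, a population-only GLMM (family intercept whenever
family structure exists; observation intercept per the dispersion rule)
yields one log OR and squared SE per derived population — 2 populations ×
4 subsets = 8 effects per regime.

## Meta-analysis (`thermoadapt.meta`)

`y_ij = μ + β·pop_ij + u_j + ε_ij` with `u_j ~ N(0, τ²)` per experiment
and `ε_ij ~ N(0, v_ij)` known.  The marginal covariance is
`diag(v) + τ²·ZZᵀ`; β is profiled out by GLS and τ² optimized on the log
scale (lower bound 0, tolerance 1e-10, with an explicit τ² = 0
comparison).  τ² is *reported* from REML; likelihood-ratio tests of fixed
effects refit both models by full ML, the regime under which the χ²
reference is valid.  When k equals the number of fixed coefficients the
restricted likelihood carries no information about τ², which is then
pinned at 0.

The moderator is treatment-coded (intercept = VCH97 mean, indicator for
VCH08), so the 1-df moderator test asks whether the two derived
populations differ.  Because a 1-df χ² could equally refer to a test of
the overall mean, a 1-df "overall mean = 0" test (intercept model vs
zero-mean model) is exposed alongside.

## Dominance (`thermoadapt.dominance`)

Populations are placed on a resurrection time axis (ancestor = 0, first
revival = 1, second = 2).  The log-odds slope through time is the
inverse-variance-weighted least-squares slope through the origin — the
ancestor is its own reference and is anchored at (0, 0) with zero
variance.  Unweighted slopes are available as an option (the weighting
convention in the source analyses is not documented).

The dominance coefficient is the slope ratio `ĥ = b_crossed / b_own`,
under the model that crossed offspring carry the paternally transmitted
evolved alleles heterozygously: h = 0.5 means fully additive (half the
additive effect transmitted through males), h = 0 fully recessive.  The
CI is a percentile parametric bootstrap (default 10,000 draws, seeded)
resampling both slopes from `N(slope, SE²)`.  When the own-bred slope is
within 2 SE of zero the ratio is unstable and the estimate is flagged
rather than suppressed.

## Selection simulation (`thermoadapt.selection`)

Fitnesses 1 : 1+hs : 1+s for aa : Aa : AA (h is the dominance of the
*beneficial* allele; "recessive beneficial" is h = 0).  The deterministic
recursion updates p via the standard single-locus mean-fitness formula;
the stochastic model draws 2N allele copies binomially around the
deterministic update each generation, operating purely in frequency
space so N = 10⁶–10⁷ costs O(generations) per replicate.  Defaults:
p₀ = 1/(2N) (a new mutation); a standing-variation preset
p₀ = sqrt(μ/s) with μ = 10⁻⁸ is provided because the starting frequency
of the original analysis is not documented.  Both deterministic and
stochastic trajectories are exposed and labelled in the sweep report.

## Mitotype pipeline (`thermoadapt.mitotypes`)

**Calling.** For each individually sequenced (effectively homoplasmic)
sample, the carried base at a position is the majority base if its
fraction ≥ `min_alt_fraction` (default 0.8) and coverage ≥ `min_coverage`
(default 20); both thresholds are exposed on the CLI since the upstream
pipeline they replace did not document its values.  A position is a SNP
when called individuals disagree.  With no external reference sequence in
the base-fraction format, the reference base is inferred as the modal
called base (alphabetical tie-break); this is unambiguous whenever the
derived allele is carried by a minority of sequenced individuals, which
the synthetic generators guarantee and which held for the motivating
dataset (largest sharing group: 3 of 10).  Indels never enter the
long-format table and are excluded by construction.  Three
reference regions with collapsed short-read coverage
(14045–14394, 14682–14835, 15409–15806, 1-based inclusive) are excluded
by default.

**Classification and grouping.** SNPs carried by ≥ 2 individuals are
*shared*, by exactly one *private*.  Identical non-empty shared-SNP
profiles define a mitotype; individuals without shared SNPs are singleton
mitotypes.  Without recombination, shared-SNP carrier sets must be
laminar (pairwise nested or disjoint); partial overlaps are flagged as
recombination-like conflicts, never silently merged.  The dendrogram is
single linkage on Hamming distances between shared-SNP presence profiles
(profile-less individuals thus group as siblings), rendered to Newick via
scikit-bio.

**Envelopes.** A mitotype's per-year envelope is the maximum of its
shared-SNP pool frequencies (private-SNP frequencies for singletons),
with replicate pools of a year averaged first.  The maximum is taken per
year by default — the tightest upper envelope consistent with the
"most frequent SNP" rule — with a global-argmax variant as an option.
Pool fractions are used raw, without coverage reweighting across
positions.  A SNP absent from a year's pool contributes frequency 0 and
is logged.  Fig-style output filtering (e.g. only private series above
1%) is applied at the display layer, never during computation.

**No-recombination check.** Per mitotype and year, the summed private-SNP
pool frequencies must not exceed the maximum shared-SNP frequency; the
tolerance is 3 pooled-binomial SDs at the year's mean pool coverage, and
signed margins are reported.

## Synthetic-data generators (`thermoadapt.simulate`)

The generators emulate exactly the structure the analyses assume, with
defaults chosen once to mirror the study conditions:

* **Survival**: binomial tubes of 10 under a logit-linear truth.  The
  default truth has baseline logit 1.0 (≈ 73% survival), a −1.5 cost of
  the hot regime, derived-population rescue at the hot regime of +0.8
  (first revival) and +1.2 (second), σ_fam = 0.5 and σ_obs = 0.3.  The
  parental-acclimation layout reproduces the documented per-population
  offspring totals (4470/3500/4720 over 54/48/56 families; 12,690
  individuals) by integer arithmetic; the additive (crossing) layout
  totals 1830 individuals.
* **Adaptation history**: own-bred effect `δ·t`, crossed effect
  `h·δ·t` (single-locus-equivalent aggregation of the half-transmission
  argument), Gaussian noise with its variance attached.
* **Mitochondrial pool-seq**: a recombination-free population of lineages
  with per-year frequencies (study-structure preset: six mitotypes at
  stable frequencies summing to 0.80 over eight years, 7 shared and 32
  private SNPs among ten individuals).  Each private SNP marks a
  sub-lineage: members of multi-individual mitotypes split their lineage
  share equally across their private SNPs (so summed private frequencies
  never exceed the mitotype frequency), while a singleton's private SNPs
  are nested with halving shares, the oldest marking the whole lineage.
  Pool coverage is Poisson (default mean 3000; individuals 200), read
  sampling is multinomial, and base error (default 10⁻³) is spread
  symmetrically over the three non-true bases.  An analytic mode returns
  exact expectations (the infinite-coverage limit).

What the generators deliberately do **not** model: tube-within-family
correlation beyond the family intercept, temporal autocorrelation of pool
samples beyond the specified frequencies, read-level artefacts (mapping
bias, strand effects, indels), heteroplasmy, and any life-history
dynamics.  Passing recovery tests therefore demonstrates correctness of
the estimators under their own assumptions, not robustness to real-data
violations of them.

## Reproducibility and problem sizes

One global seed; each stage draws from an independent substream keyed by
`(seed, stage name)` (CRC-32 into a `SeedSequence`), so identical
configurations are byte-identical and stages are reproducible in
isolation.  All fitted quantities are echoed as `key=value` log lines.

The test suite and `scripts/acceptance.py` use desk-scale problem sizes
chosen as the package's own defaults: 200 replicates (tests; 100 in the
script) of the 60-family × 4-tube survival recovery, 500 dominance
recoveries and 500 null meta-analyses, 40 stochastic Wright–Fisher
replicates at N = 10⁶, and 10–15 randomized mitotype structures (≤ 12
individuals, ≤ 60 SNPs).  Archived field data are not required anywhere;
where the original study's headline statistics depend on its archived
data, the pipeline exposes the identical computational path and is
validated on synthetic data with the same structure instead.

## Known limitations

* Quadrature is non-adaptive; random-intercept SDs far above ~3 on the
  logit scale (not plausible for survival data of this kind) would need
  more nodes.
* Separation is flagged but not penalized; data subsets with empty cells
  should be handled by the caller.
* The meta-analysis supports one grouping level (experiment) and known
  sampling variances, as the design requires — not multivariate effects
  or publication-bias diagnostics.
* The dominance estimator assumes maternal-lineage effects cancel in the
  crossing design and aggregates multi-locus dominance into a single h.
* Mitotype assignment requires derived alleles to be minority alleles
  among sequenced individuals; SNPs that cannot be assigned to a laminar
  sharing structure are reported as conflicts rather than resolved.
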