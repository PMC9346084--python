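# thermoadapt

Analysis toolkit for **resurrection-ecology studies of thermal adaptation**:
common-garden survival experiments on populations revived from dated
diapause-egg banks (e.g. *Artemia franciscana* introduced from a temperate
to a tropical saltern), with a mitochondrial pool-seq arm tracking maternal
lineages through time.

It is written for researchers who need to answer, from such a design:

1. **Did the derived populations become more heat-tolerant?**
   Tube-level survival counts are modelled with binomial GLMMs
   (logit link, family and observation-level random intercepts), and the
   log odds ratio of each derived population against the ancestor is
   combined across experiments by a multilevel random-effects
   meta-analysis.
2. **Is the change additively genetic?**  Crossing derived males to
   ancestral-stock females makes any paternally transmitted alleles
   heterozygous; the ratio of the crossed to the own-bred log-odds slope
   through resurrection time estimates the dominance coefficient *h* of
   the evolved change (0.5 = additive, 0 = recessive).
3. **Could such alleles have swept?**  Wright–Fisher simulation of a
   beneficial allele with fitnesses 1 : 1+*hs* : 1+*s* asks whether an
   allele with the inferred dominance could reach high frequency within
   the observed number of generations.
4. **Did the mitochondrial population change?**  From per-position base
   fractions of individually sequenced animals and pooled cyst samples,
   shared SNPs (carried by ≥ 2 individuals) define mitotypes, private SNPs
   bound within-mitotype diversity, and per-year frequency envelopes track
   each mitotype through the egg bank — with a no-recombination
   consistency check (summed private-SNP frequencies cannot exceed the
   defining shared-SNP frequency).

Every stage has a matching synthetic-data generator, so the full pipeline
is testable end to end without any external download.

## Core models

Survival of tube *i* in family *f*: `y_i ~ Binomial(n_i, p_i)`,
`logit(p_i) = x_iᵝ + u_f + e_i`, `u_f ~ N(0, σ²_fam)`,
`e_i ~ N(0, σ²_obs)`; the marginal likelihood integrates *u* and *e* out
by (nested) Gauss–Hermite quadrature and nested models are compared by
likelihood-ratio χ² tests, with Tukey post hocs on factor levels.

Meta-analysis of effects `y_ij` (log OR, experiment *j*, sampling variance
`v_ij`): `y_ij = μ + β·pop_ij + u_j + ε_ij`, `u_j ~ N(0, τ²)`,
`ε_ij ~ N(0, v_ij)`; τ² by REML, fixed-effect tests by ML likelihood
ratios.

Dominance: `ĥ = b_crossed / b_own` where each *b* is the
inverse-variance-weighted slope of log odds through time anchored at the
ancestor (0, 0); CI by parametric bootstrap.

Selection: `p' = [p²(1+s) + p(1−p)(1+hs)] / w̄` with binomial resampling
of 2*N* copies per generation (frequency space, so *N* = 10⁷ is cheap).

## Worked example

Estimate dominance from simulated own-bred vs crossed trajectories with a
nearly recessive truth (*h* = 0.1), then ask whether such an allele could
sweep:

```python
from thermoadapt import (SelectionParams, deterministic_trajectory,
                         simulate_adaptation_history, dominance_from_effects)

effects = simulate_adaptation_history(h_true=0.1, delta=1.2, times=[0, 1, 2],
                                      sampling_sd=0.08, seed=7)
est, own, crossed = dominance_from_effects(effects, n_boot=10_000, seed=7)
print(f"own-bred slope     : {own.slope:+.3f} (SE {own.se:.3f})")
print(f"crossed slope      : {crossed.slope:+.3f} (SE {crossed.se:.3f})")
print(f"dominance h        : {est.h:.3f}  95% CI [{est.ci[0]:.3f}, {est.ci[1]:.3f}]")

traj = deterministic_trajectory(SelectionParams(s=0.3, h=0.1, N=10**6,
                                                generations=100))
print(f"p after 100 gen    : {traj[-1]:.2e}  (s=0.3, h=0.1, p0=1/2N)")
```

prints

```
own-bred slope     : +1.196 (SE 0.036)
crossed slope      : +0.081 (SE 0.036)
dominance h        : 0.068  95% CI [0.009, 0.127]
p after 100 gen    : 9.61e-06  (s=0.3, h=0.1, p0=1/2N)
```

The own-bred populations gain ~1.2 log-odds of survival per resurrection
step while the crossed ones gain almost nothing, so the change behaves as
almost fully recessive — and a recessive allele under even strong
selection (*s* = 0.3) barely moves from a single-copy start in 100
generations (final frequency ~10⁻⁵), far from a sweep.

The same stages are available as a CLI
(`thermoadapt simulate-survival | fit-survival | meta | dominance | sweep
| simulate-mito | mitotypes`), each writing TSV/JSON reports.

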