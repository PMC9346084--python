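"""Wright–Fisher dynamics of a beneficial allele with arbitrary dominance.

Genotype fitnesses are 1 : 1+hs : 1+s for aa : Aa : AA, where A is the
beneficial allele, s >= 0 its selection coefficient and h in [0, 1] its
dominance (h = 0 recessive, 0.5 additive, 1 dominant).  The deterministic
recursion updates the allele frequency p by

    p' = [p^2 (1+s) + p(1-p)(1+hs)] / wbar,
    wbar = p^2 (1+s) + 2 p (1-p)(1+hs) + (1-p)^2,

and the stochastic model resamples 2N allele copies binomially around the
deterministic update each generation.  Sampling operates in frequency
space, so population sizes of 10^6–10^7 cost the same as small ones.

The feasibility question asked here: can an allele with the dominance level
inferred from the crossing experiments (h ~ 0.1) sweep from rarity to high
frequency within ~100 generations under even strong selection (s = 0.3)?
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import log_kv
from .errors import ModelError


@dataclass(frozen=True)
class SelectionParams:
    s: float = 0.3
    h: float = 0.1
    N: int = 1_000_000
    p0: float | None = None  # default: a single new mutant copy, 1/(2N)
    generations: int = 100

    def __post_init__(self):
        if self.s < 0:
            raise ModelError("selection coefficient s must be >= 0")
        if not 0 <= self.h <= 1:
            raise ModelError("dominance h must lie in [0, 1]")
        if self.N < 1:
            raise ModelError("population size N must be >= 1")
        p0 = self.initial_frequency
        if not 0 <= p0 <= 1:
            raise ModelError("initial frequency p0 must lie in [0, 1]")
        if self.generations < 0:
            raise ModelError("generations must be >= 0")

    @property
    def initial_frequency(self) -> float:
        return 1.0 / (2 * self.N) if self.p0 is None else self.p0


def standing_variation_p0(s: float, mu: float = 1e-8) -> float:
    """Mutation–selection balance starting frequency sqrt(mu/s) for a
    recessive deleterious-before-shift allele kept at standing variation."""
    if s <= 0:
        raise ModelError("standing-variation preset needs s > 0")
    return float(np.sqrt(mu / s))


def selection_update(p, s: float, h: float):
    """One generation of the deterministic recursion (vectorized)."""
    p = np.asarray(p, float)
    q = 1.0 - p
    w_AA, w_Aa, w_aa = 1.0 + s, 1.0 + h * s, 1.0
    wbar = p * p * w_AA + 2 * p * q * w_Aa + q * q * w_aa
    out = np.where(wbar > 0, (p * p * w_AA + p * q * w_Aa) / np.where(wbar > 0, wbar, 1.0), p)
    return out if out.ndim else float(out)


def deterministic_trajectory(params: SelectionParams) -> np.ndarray:
    """Allele frequencies p_0..p_G under the deterministic recursion."""
    p = params.initial_frequency
    out = np.empty(params.generations + 1)
    out[0] = p
    for t in range(1, params.generations + 1):
        p = selection_update(p, params.s, params.h)
        out[t] = p
    return out


def wright_fisher_trajectory(
    params: SelectionParams, n_replicates: int = 1, seed: int = 0
) -> np.ndarray:
    """Stochastic trajectories, shape ``(n_replicates, generations + 1)``.

    Each generation draws the allele count among 2N copies binomially with
    success probability equal to the deterministic update of the current
    frequency (frequency-space sampling; never individual-based).
    """
    rng = np.random.default_rng(seed)
    two_n = 2 * params.N
    p = np.full(n_replicates, params.initial_frequency)
    # honor the precondition that N*p0 rounds to a representable count
    p = np.round(p * two_n) / two_n
    out = np.empty((n_replicates, params.generations + 1))
    out[:, 0] = p
    for t in range(1, params.generations + 1):
        p_det = selection_update(p, params.s, params.h)
        p = rng.binomial(two_n, p_det) / two_n
        out[:, t] = p
    return out


@dataclass
class SweepReport:
    params: SelectionParams
    target_freq: float
    n_replicates: int
    seed: int
    deterministic_final: float
    deterministic_generations_to_target: int | None
    fraction_reaching_target: float
    deterministic_trajectory: np.ndarray = field(repr=False)

    def summary_dict(self) -> dict:
        return {
            "s": self.params.s, "h": self.params.h, "N": self.params.N,
            "p0": self.params.initial_frequency,
            "generations": self.params.generations,
            "target_freq": self.target_freq,
            "n_replicates": self.n_replicates, "seed": self.seed,
            "deterministic_final": self.deterministic_final,
            "deterministic_generations_to_target":
                self.deterministic_generations_to_target,
            "fraction_reaching_target": self.fraction_reaching_target,
        }


def sweep_feasibility(
    params: SelectionParams,
    target_freq: float = 0.5,
    n_replicates: int = 100,
    seed: int = 0,
) -> SweepReport:
    """Assess whether the allele can reach ``target_freq`` within the run.

    Combines the deterministic trajectory (final frequency and first
    generation reaching the target, if any) with the fraction of
    stochastic replicates whose final frequency is at least the target.
    """
    if not 0 < target_freq <= 1:
        raise ModelError("target_freq must lie in (0, 1]")
    det = deterministic_trajectory(params)
    reached = np.nonzero(det >= target_freq)[0]
    gen_to_target = int(reached[0]) if len(reached) else None
    stoch = wright_fisher_trajectory(params, n_replicates=n_replicates, seed=seed)
    frac = float(np.mean(stoch[:, -1] >= target_freq))
    report = SweepReport(
        params=params, target_freq=target_freq, n_replicates=n_replicates,
        seed=seed, deterministic_final=float(det[-1]),
        deterministic_generations_to_target=gen_to_target,
        fraction_reaching_target=frac, deterministic_trajectory=det,
    )
    log_kv("sweep", s=params.s, h=params.h, N=params.N,
           p0=params.initial_frequency, det_final=report.deterministic_final,
           frac_reaching=frac)
    return report
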