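"""Dominance of the evolved survival change, from crossing experiments.

The derived populations can be scored at "time" 0, 1 and 2 (ancestral
population, first and second resurrection time points).  Survival log odds
ratios against the ancestor then define two trajectories: one for
populations bred within their own lineage (evolved alleles homozygous) and
one for populations crossed to ancestral-stock females (paternally
transmitted alleles heterozygous).  If the phenotypic change is genetic
with dominance coefficient h, the crossed trajectory's slope through time
is h times the own-bred slope — h = 0.5 for purely additive effects, since
roughly half of the additive effects are paternally transmitted — so the
slope ratio estimates h.  Confidence intervals come from a parametric
bootstrap over the two slope estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import log_kv
from .errors import ModelError
from .survival import EffectSize

#: Time codes of the sampled populations on the resurrection axis.
POPULATION_TIME = {"SFB84": 0.0, "VCH97": 1.0, "VCH08": 2.0}


@dataclass(frozen=True)
class SlopeEstimate:
    slope: float
    se: float
    cross_status: str

    def __post_init__(self):
        if not self.se > 0:
            raise ModelError("slope SE must be > 0")


@dataclass(frozen=True)
class DominanceEstimate:
    h: float
    ci: tuple[float, float]
    method: str
    unstable: bool = False


def _time_of(effect: EffectSize) -> float:
    if effect.time is not None:
        return float(effect.time)
    try:
        return POPULATION_TIME[effect.population]
    except KeyError:
        raise ModelError(f"no time code for population {effect.population!r}")


def log_odds_slope(effects: list[EffectSize], weighted: bool = True) -> SlopeEstimate:
    """Slope of the log odds score through time, anchored at the origin.

    The ancestral population is its own reference, so the point (0, 0)
    is exact and the regression is through the origin.  With
    ``weighted=True`` points are weighted by inverse sampling variance.
    """
    if not effects:
        raise ModelError("no effects supplied")
    status = {e.cross_status for e in effects}
    if len(status) != 1:
        raise ModelError("mix of own and crossed effects in one slope")
    t = np.array([_time_of(e) for e in effects])
    y = np.array([e.log_odds_ratio for e in effects])
    v = np.array([e.variance for e in effects])
    keep = t > 0  # the origin is the anchor, not a data point
    t, y, v = t[keep], y[keep], v[keep]
    if len(np.unique(t)) < 1 or len(t) == 0:
        raise ModelError("need effects at >= 1 nonzero time point")
    w = 1.0 / v if weighted else np.ones_like(v)
    swt2 = float(np.sum(w * t * t))
    slope = float(np.sum(w * t * y) / swt2)
    if weighted:
        var = 1.0 / swt2
    else:
        # unweighted slope still inherits the known sampling variances
        var = float(np.sum(t * t * v) / np.sum(t * t) ** 2)
    est = SlopeEstimate(slope=slope, se=float(np.sqrt(var)),
                        cross_status=status.pop())
    log_kv("log_odds_slope", cross_status=est.cross_status,
           slope=est.slope, se=est.se)
    return est


def estimate_dominance(
    uncrossed: SlopeEstimate,
    crossed: SlopeEstimate,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> DominanceEstimate:
    """Estimate the dominance coefficient h as the ratio of the crossed to
    the own-bred log-odds slope.

    Under the heterozygote-scaling convention (heterozygote effect = h x
    homozygote effect) h = 0 is fully recessive, 0.5 additive, 1 dominant.
    The percentile CI resamples both slopes from Normal(slope, SE^2).  If
    the own-bred slope is indistinguishable from zero (|slope| < 2 SE) the
    ratio is unstable and the estimate is flagged.
    """
    if uncrossed.slope == 0:
        raise ModelError("own-bred slope is zero; dominance undefined")
    h = crossed.slope / uncrossed.slope
    rng = np.random.default_rng(seed)
    u = rng.normal(uncrossed.slope, uncrossed.se, n_boot)
    c = rng.normal(crossed.slope, crossed.se, n_boot)
    ratios = c / u
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(ratios, [alpha, 1 - alpha])
    unstable = abs(uncrossed.slope) < 2 * uncrossed.se
    est = DominanceEstimate(
        h=float(h), ci=(float(min(lo, h)), float(max(hi, h))),
        method=f"slope-ratio, parametric bootstrap n={n_boot}",
        unstable=bool(unstable),
    )
    log_kv("dominance", h=est.h, lo=est.ci[0], hi=est.ci[1], unstable=unstable)
    return est


def dominance_from_effects(
    effects: list[EffectSize],
    n_boot: int = 10_000,
    seed: int = 0,
    weighted: bool = True,
) -> tuple[DominanceEstimate, SlopeEstimate, SlopeEstimate]:
    """Convenience wrapper: split effects by cross status, compute both
    slopes and the dominance estimate."""
    own = [e for e in effects if e.cross_status == "own"]
    crossed = [e for e in effects if e.cross_status == "crossed"]
    if not own or not crossed:
        raise ModelError("need both own and crossed effect trajectories")
    s_own = log_odds_slope(own, weighted=weighted)
    s_cross = log_odds_slope(crossed, weighted=weighted)
    return estimate_dominance(s_own, s_cross, n_boot=n_boot, seed=seed), s_own, s_cross
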