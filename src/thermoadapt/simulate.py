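"""Synthetic data generators with the statistical structure the analyses
assume.

Three generators are provided:

* :func:`simulate_survival_experiment` draws tube-level binomial survival
  counts from a logit-scale linear model with configurable fixed effects,
  a family random intercept (tubes from one parental couple share a
  deviate) and an observation-level intercept (overdispersion);
* :func:`simulate_adaptation_history` draws the own-bred vs crossed
  log-odds trajectories through resurrection time for a known dominance
  coefficient, the ground truth for the dominance estimator;
* :func:`simulate_mito_dataset` emits per-individual and pooled
  base-fraction tables for a recombination-free mitotype population, with
  Poisson coverage, binomial read sampling and symmetric base error.

Every generator is deterministic given ``(parameters, seed)``.  The two
thermal regimes enter only as categorical labels; their hour-by-hour
temperature profiles never participate in any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, SchemaError
from .io import FACTOR_LEVELS, validate_survival_frame
from .mitotypes import BASES, BaseFractionTable, SampleInfo
from .survival import EffectSize

# ---------------------------------------------------------------------------
# survival experiments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectSpec:
    """True logit-scale effects for the survival generator.

    ``effects`` maps factor-level conditions to logit shifts: a tube
    receives a shift when *all* conditions of that entry match its factor
    levels, so interactions are expressed as multi-factor conditions.
    """

    baseline_logit: float = 0.0
    effects: tuple[tuple[tuple[tuple[str, str], ...], float], ...] = ()
    sigma_family: float = 0.0
    sigma_obs: float = 0.0

    def __post_init__(self):
        if self.sigma_family < 0 or self.sigma_obs < 0:
            raise ConfigError("random-effect SDs must be >= 0")
        for conditions, _ in self.effects:
            for factor, level in conditions:
                if factor not in FACTOR_LEVELS:
                    raise ConfigError(f"unknown factor {factor!r} in effect spec")
                if level not in FACTOR_LEVELS[factor]:
                    raise ConfigError(f"unknown level {level!r} for factor {factor!r}")

    @staticmethod
    def build(baseline_logit=0.0, effects=None, sigma_family=0.0, sigma_obs=0.0):
        """Construct from a ``{conditions_dict: shift}``-style list of
        ``(dict, shift)`` pairs."""
        packed = tuple(
            (tuple(sorted(cond.items())), float(shift))
            for cond, shift in (effects or [])
        )
        return EffectSpec(baseline_logit, packed, sigma_family, sigma_obs)

    def linear_predictor(self, row: dict) -> float:
        eta = self.baseline_logit
        for conditions, shift in self.effects:
            if all(row.get(f) == l for f, l in conditions):
                eta += shift
        return eta


def study_effect_spec() -> EffectSpec:
    """Default truth emulating the study conditions: survival around
    expit(1) ~ 0.73 under the native regime, a strong survival cost of the
    hot regime, and derived-population rescue at the hot regime that grows
    with resurrection time; moderate family and overdispersion variance."""
    return EffectSpec.build(
        baseline_logit=1.0,
        effects=[
            ({"regime": "T_VCH"}, -1.5),
            ({"population": "VCH97", "regime": "T_VCH"}, 0.8),
            ({"population": "VCH08", "regime": "T_VCH"}, 1.2),
        ],
        sigma_family=0.5,
        sigma_obs=0.3,
    )


@dataclass
class ExperimentDesign:
    """A concrete layout of tubes: one template row per tube with its
    factor levels, family id and number of individuals."""

    experiment: str
    tubes: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if (self.tubes["n_total"] < 1).any():
            raise ConfigError("individuals per tube must be >= 1")

    @property
    def n_individuals(self) -> int:
        return int(self.tubes["n_total"].sum())


def _tube_rows(experiment, rows):
    defaults = {
        "experiment": experiment, "cross_status": "own", "clutch": "NA",
        "parental_treatment": "NA", "phase1_regime": "NA", "microbiome": "NA",
        "family_id": "NA",
    }
    df = pd.DataFrame([{**defaults, **r} for r in rows])
    df["tube_id"] = [f"{experiment}-{i:05d}" for i in range(len(df))]
    return df


def additive_design(n_per_tube: int = 10) -> ExperimentDesign:
    """Common-garden design for additive genetic effects: males of each
    population mass-crossed to ancestral stock females, offspring reared
    under both regimes.  30 + 31 tubes of 10 per population across the two
    regimes give the experiment's 1830 individuals."""
    rows = []
    for pop in ("SFB84", "VCH97", "VCH08"):
        for regime, n_tubes in (("T_SFB", 30), ("T_VCH", 31)):
            for _ in range(n_tubes):
                rows.append({"population": pop, "regime": regime,
                             "cross_status": "crossed", "n_total": n_per_tube})
    return ExperimentDesign("additive", _tube_rows("additive", rows))


#: Per-population layout of the parental-acclimation experiment:
#: (families, offspring tested).  Offspring are reared in tubes of 10 split
#: over clutch (1st/2nd) x regime cells, so totals are exact by integer
#: arithmetic: 4470 + 3500 + 4720 = 12,690 individuals overall.
PARENTAL_LAYOUT = {
    "SFB84": (54, 4470),
    "VCH97": (48, 3500),
    "VCH08": (56, 4720),
}


def parental_design(n_per_tube: int = 10) -> ExperimentDesign:
    rows = []
    treatments = ("control", "mother", "father")
    for pop, (n_fam, total) in PARENTAL_LAYOUT.items():
        n_tubes, rem = divmod(total, n_per_tube)
        if rem:
            raise ConfigError("population total must be divisible by tube size")
        base, extra = divmod(n_tubes, n_fam)
        cells = [("1", "T_SFB"), ("1", "T_VCH"), ("2", "T_SFB"), ("2", "T_VCH")]
        for f in range(n_fam):
            fam_tubes = base + (1 if f < extra else 0)
            treatment = treatments[f % 3]
            for t in range(fam_tubes):
                clutch, regime = cells[t % 4]
                rows.append({
                    "population": pop, "regime": regime, "clutch": clutch,
                    "parental_treatment": treatment,
                    "family_id": f"{pop}-F{f + 1:02d}", "n_total": n_per_tube,
                })
    return ExperimentDesign("parental", _tube_rows("parental", rows))


def juvenile_design(n_families: int = 20, tubes_per_cell: int = 1,
                    n_per_tube: int = 10) -> ExperimentDesign:
    """Juvenile-acclimation design: families contribute tubes to every
    (early regime, test regime) cell."""
    rows = []
    for pop in ("SFB84", "VCH97", "VCH08"):
        for f in range(n_families):
            for phase1 in ("T_SFB", "T_VCH"):
                for regime in ("T_SFB", "T_VCH"):
                    for _ in range(tubes_per_cell):
                        rows.append({
                            "population": pop, "regime": regime,
                            "phase1_regime": phase1,
                            "family_id": f"{pop}-J{f + 1:02d}",
                            "n_total": n_per_tube,
                        })
    return ExperimentDesign("juvenile", _tube_rows("juvenile", rows))


def microbiome_design(tubes_per_cell: int = 10, n_per_tube: int = 10) -> ExperimentDesign:
    rows = []
    for pop in ("SFB84", "VCH97", "VCH08"):
        for micro in ("SFB", "VCH", "LAB"):
            for regime in ("T_SFB", "T_VCH"):
                for _ in range(tubes_per_cell):
                    rows.append({"population": pop, "regime": regime,
                                 "microbiome": micro, "n_total": n_per_tube})
    return ExperimentDesign("microbiome", _tube_rows("microbiome", rows))


def simulate_survival_experiment(
    design: ExperimentDesign, effects: EffectSpec, seed: int = 0
) -> pd.DataFrame:
    """Draw tube survival counts: n_alive ~ Binomial(n_total, expit(eta))
    with eta = baseline + fixed shifts + family deviate + tube deviate."""
    rng = np.random.default_rng(seed)
    df = design.tubes.copy()
    fams = df["family_id"].to_numpy()
    fam_codes, fam_uniq = pd.factorize(fams)
    u = rng.normal(0.0, effects.sigma_family, len(fam_uniq))
    u = np.where(fam_uniq == "NA", 0.0, u)  # no family structure, no deviate
    e = rng.normal(0.0, effects.sigma_obs, len(df))
    eta = np.array([effects.linear_predictor(r) for r in df.to_dict("records")])
    eta = eta + u[fam_codes] + e
    df["n_alive"] = rng.binomial(df["n_total"].to_numpy(int), expit(eta))
    return validate_survival_frame(df)


# ---------------------------------------------------------------------------
# adaptation history (dominance ground truth)
# ---------------------------------------------------------------------------

_TIME_POPULATION = {0.0: "SFB84", 1.0: "VCH97", 2.0: "VCH08"}


def simulate_adaptation_history(
    h_true: float,
    delta: float,
    times: list[float],
    sampling_sd: float,
    seed: int = 0,
) -> list[EffectSize]:
    """Own-bred and crossed log-odds effects through resurrection time.

    Own-bred populations carry the evolved change homozygously, so their
    expected effect at time t is ``delta * t``.  Crossed populations carry
    paternally transmitted alleles heterozygously, scaling the expectation
    by the dominance coefficient: ``h_true * delta * t``.  Gaussian noise
    with SD ``sampling_sd`` is added and the matching sampling variance is
    attached to every effect.
    """
    if not times:
        raise ConfigError("times must be nonempty")
    if sampling_sd < 0:
        raise ConfigError("sampling_sd must be >= 0")
    if not 0 <= h_true <= 1:
        raise ConfigError("h_true must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    var = max(sampling_sd ** 2, 1e-12)
    out = []
    for status, scale in (("own", 1.0), ("crossed", h_true)):
        for t in times:
            y = scale * delta * t + rng.normal(0.0, sampling_sd)
            out.append(EffectSize(
                log_odds_ratio=float(y), variance=var,
                population=_TIME_POPULATION.get(float(t), f"t{t:g}"),
                experiment="adaptation_history", regime="T_VCH",
                cross_status=status, time=float(t),
            ))
    return out


# ---------------------------------------------------------------------------
# mitochondrial pool-seq
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SNPDef:
    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref not in BASES or self.alt not in BASES or self.ref == self.alt:
            raise SchemaError(f"invalid substitution {self.ref}>{self.alt}")

    @property
    def snp_id(self) -> str:
        return f"{self.position}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class IndividualSpec:
    individual_id: str
    private_snps: tuple[SNPDef, ...] = ()
    weight: float = 1.0  # sub-lineage share of the mitotype frequency

    def private_shares(self, singleton: bool) -> tuple[float, ...]:
        """Population share (of the mitotype frequency) of each private SNP.

        For members of multi-individual mitotypes the member's weight is
        split equally over its private SNPs, so summed private frequencies
        within the mitotype never exceed the mitotype frequency.  For a
        singleton lineage the private SNPs are nested sub-mutations: the
        oldest marks the entire lineage (share 1) and each further one
        halves the share, so the most frequent private SNP tracks the
        lineage frequency exactly.
        """
        k = len(self.private_snps)
        if k == 0:
            return ()
        if singleton:
            return tuple(2.0 ** -j for j in range(k))
        return tuple(self.weight / k for _ in range(k))


@dataclass(frozen=True)
class MitoLineage:
    lineage_id: str
    shared_snps: tuple[SNPDef, ...]
    members: tuple[IndividualSpec, ...]
    frequencies: dict[int, float]  # year -> population frequency

    @property
    def singleton(self) -> bool:
        return len(self.shared_snps) == 0


@dataclass
class MitotypePopulation:
    """Ground-truth recombination-free mitochondrial population.

    Non-singleton lineages are marked by shared SNPs carried by all their
    (>= 2) sequenced members; singleton lineages have one member and no
    shared SNP.  Each member's private SNPs segregate at ``weight`` times
    the lineage frequency (its sub-lineage share), which guarantees the
    no-recombination envelope inequality by construction.
    """

    reference_length: int
    years: list[int]
    lineages: list[MitoLineage]

    def __post_init__(self):
        seen_pos: set[int] = set()
        for lin in self.lineages:
            if lin.singleton:
                if len(lin.members) != 1:
                    raise SchemaError(f"{lin.lineage_id}: singleton lineages have "
                                      "exactly one member")
            elif len(lin.members) < 2:
                raise SchemaError(f"{lin.lineage_id}: shared SNPs need >= 2 members")
            wsum = sum(m.weight for m in lin.members)
            if wsum > 1 + 1e-9:
                raise SchemaError(f"{lin.lineage_id}: member weights sum to > 1")
            for snp in lin.shared_snps + tuple(
                    s for m in lin.members for s in m.private_snps):
                if snp.position in seen_pos:
                    raise SchemaError(f"SNP position {snp.position} reused")
                if not 1 <= snp.position <= self.reference_length:
                    raise SchemaError(f"SNP position {snp.position} off reference")
                seen_pos.add(snp.position)
        for year in self.years:
            total = sum(lin.frequencies.get(year, 0.0) for lin in self.lineages)
            if total > 1 + 1e-9:
                raise SchemaError(f"lineage frequencies sum to > 1 in {year}")

    @property
    def individuals(self) -> list[IndividualSpec]:
        return [m for lin in self.lineages for m in lin.members]

    def snp_frequency(self, snp: SNPDef, year: int) -> float:
        """True population frequency of the lineage carrying ``snp``."""
        for lin in self.lineages:
            if snp in lin.shared_snps:
                return lin.frequencies.get(year, 0.0)
            for m in lin.members:
                if snp in m.private_snps:
                    share = m.private_shares(lin.singleton)[m.private_snps.index(snp)]
                    return share * lin.frequencies.get(year, 0.0)
        raise SchemaError(f"unknown SNP {snp.snp_id}")

    def all_snps(self) -> list[SNPDef]:
        out = []
        for lin in self.lineages:
            out.extend(lin.shared_snps)
            for m in lin.members:
                out.extend(m.private_snps)
        return sorted(out, key=lambda s: s.position)

    def carriers(self, snp: SNPDef) -> set[str]:
        for lin in self.lineages:
            if snp in lin.shared_snps:
                return {m.individual_id for m in lin.members}
            for m in lin.members:
                if snp in m.private_snps:
                    return {m.individual_id}
        raise SchemaError(f"unknown SNP {snp.snp_id}")


def study_mitotype_population() -> MitotypePopulation:
    """A fixed population mirroring the structure reported for the field
    system: ten sequenced individuals, three multi-member mitotypes (a
    pair, a pair and a trio, jointly marked by seven shared SNPs), three
    singleton individuals, 32 private SNPs, and stable per-year lineage
    frequencies summing to ~0.8 over the eight sampled years."""
    years = [1984, 1987, 1988, 1993, 1994, 1997, 1998, 2008]
    rng = np.random.default_rng(20080413)  # fixed structure, not a dial
    positions = iter(rng.choice(np.arange(100, 15000), size=60, replace=False))
    alts = {"A": "G", "C": "T", "G": "T"}

    def snp():
        p = int(next(positions))
        ref = ("A", "C", "G")[p % 3]
        return SNPDef(p, ref, alts[ref])

    def stable(f):
        return {y: f for y in years}

    privates = iter(range(32))

    def member(ind, n_private, weight):
        return IndividualSpec(ind, tuple(snp() for _ in range(n_private)
                                         if next(privates, None) is not None), weight)

    lineages = [
        MitoLineage("L_7_10", (snp(), snp()),
                    (member("ind07", 3, 0.3), member("ind10", 3, 0.3)),
                    stable(0.25)),
        MitoLineage("L_5_6", (snp(), snp()),
                    (member("ind05", 3, 0.3), member("ind06", 3, 0.3)),
                    stable(0.20)),
        MitoLineage("L_2_4_8", (snp(), snp(), snp()),
                    (member("ind02", 4, 0.25), member("ind04", 3, 0.25),
                     member("ind08", 3, 0.25)),
                    stable(0.15)),
        MitoLineage("L_1", (), (member("ind01", 4, 1.0),), stable(0.08)),
        MitoLineage("L_3", (), (member("ind03", 3, 1.0),), stable(0.07)),
        MitoLineage("L_9", (), (member("ind09", 3, 1.0),), stable(0.05)),
    ]
    return MitotypePopulation(15822, years, lineages)


def random_mitotype_population(
    seed: int = 0,
    n_multi: int = 3,
    n_singletons: int = 3,
    years: list[int] | None = None,
    reference_length: int = 4000,
    max_private: int = 3,
) -> MitotypePopulation:
    """Randomized recombination-free population for property tests.

    Alt alleles of shared SNPs are always carried by a minority of the
    sequenced individuals and refs sort before alts, so the consensus
    reference inferred by the SNP caller coincides with the generating one
    and recovery can be exact.
    """
    rng = np.random.default_rng(seed)
    years = years or [1984, 1997, 2008]
    sizes = rng.integers(2, 4, n_multi)  # members per multi lineage
    n_ind = int(sizes.sum()) + n_singletons
    if n_multi and sizes.max() > n_ind // 2:
        n_singletons = max(n_singletons, int(2 * sizes.max()) - n_ind + 1)
        n_ind = int(sizes.sum()) + n_singletons
    n_lin = n_multi + n_singletons
    pos_pool = iter(rng.choice(np.arange(1, reference_length + 1),
                               size=min(reference_length, 200), replace=False))
    ref_alt = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]

    def snp():
        ref, alt = ref_alt[int(rng.integers(len(ref_alt)))]
        return SNPDef(int(next(pos_pool)), ref, alt)

    freqs = {}
    for y in years:
        raw = rng.dirichlet(np.ones(n_lin + 1))  # +1: unsampled background
        freqs[y] = raw[:n_lin]

    lineages, idx, li = [], 1, 0
    for m in range(n_multi):
        members = []
        w = rng.dirichlet(np.ones(int(sizes[m]) + 1))  # +1: unsequenced share
        for j in range(int(sizes[m])):
            priv = tuple(snp() for _ in range(int(rng.integers(0, max_private + 1))))
            members.append(IndividualSpec(f"ind{idx:02d}", priv, float(w[j])))
            idx += 1
        shared = tuple(snp() for _ in range(int(rng.integers(1, 4))))
        lineages.append(MitoLineage(
            f"L{li}", shared, tuple(members),
            {y: float(freqs[y][li]) for y in years}))
        li += 1
    for _ in range(n_singletons):
        priv = tuple(snp() for _ in range(int(rng.integers(1, max_private + 1))))
        lineages.append(MitoLineage(
            f"L{li}", (), (IndividualSpec(f"ind{idx:02d}", priv, 1.0),),
            {y: float(freqs[y][li]) for y in years}))
        idx += 1
        li += 1
    return MitotypePopulation(reference_length, years, lineages)


def simulate_mito_dataset(
    pop: MitotypePopulation,
    mean_coverage: int = 3000,
    error_rate: float = 0.001,
    seed: int = 0,
    analytic: bool = False,
    individual_coverage: int = 200,
    replicate_years: tuple[int, ...] = (),
) -> tuple[pd.DataFrame, BaseFractionTable]:
    """Base-fraction tables for the sequenced individuals and year pools.

    Individuals are homoplasmic carriers of their lineage's shared SNPs
    plus their own private SNPs.  Pool alt fractions at a SNP equal the
    carrying (sub-)lineage's population frequency, resampled binomially at
    Poisson coverage, with symmetric base error ``error_rate`` spread over
    the three non-true bases.  ``analytic=True`` is the infinite-coverage
    limit: fractions equal their expectations exactly.
    """
    if not 0 <= error_rate <= 0.01:
        raise ConfigError("error_rate must lie in [0, 0.01]")
    if mean_coverage < 1:
        raise ConfigError("mean_coverage must be >= 1")
    rng = np.random.default_rng(seed)
    snps = pop.all_snps()
    e = error_rate

    def mix(fvec):
        fvec = np.asarray(fvec, float)
        return fvec * (1 - e) + (1 - fvec) * e / 3

    records, samples = [], {}

    def emit(sample, position, fvec, cov):
        if analytic:
            frac = mix(fvec)
        else:
            c = rng.poisson(cov)
            if c == 0:
                frac = np.zeros(4)
            else:
                frac = rng.multinomial(c, mix(fvec)) / c
            cov = c
        records.append((sample, position, *frac, cov))

    genotypes = {}
    for lin in pop.lineages:
        for m in lin.members:
            sample = m.individual_id
            samples[sample] = SampleInfo("individual")
            carried = set(lin.shared_snps) | set(m.private_snps)
            genotypes[sample] = {s.snp_id: s in carried for s in snps}
            for s in snps:
                base = s.alt if s in carried else s.ref
                fvec = [1.0 if b == base else 0.0 for b in BASES]
                emit(sample, s.position, fvec, individual_coverage)

    for year in pop.years:
        reps = 2 if year in replicate_years else 1
        for r in range(1, reps + 1):
            sample = f"pool{year}" + ("" if r == 1 else f"r{r}")
            samples[sample] = SampleInfo("pool", year=year, replicate=r)
            for s in snps:
                f = pop.snp_frequency(s, year)
                fvec = [(f if b == s.alt else (1 - f if b == s.ref else 0.0))
                        for b in BASES]
                emit(sample, s.position, fvec, mean_coverage)

    frac = pd.DataFrame(
        records, columns=["sample", "position", *BASES, "coverage"]
    ).set_index(["sample", "position"])
    table = BaseFractionTable(frac, reference_length=pop.reference_length,
                              samples=samples)
    geno = pd.DataFrame(genotypes).T.sort_index()
    return geno, table
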