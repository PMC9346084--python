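"""Mitochondrial haplotype ("mitotype") tracking from base-fraction tables.

The mitogenome does not recombine, so variants carried by two or more
sequenced individuals ("shared" SNPs) mark whole maternal lineages, while
variants seen in exactly one individual ("private" SNPs) mark sub-lineages.
Individuals with identical shared-SNP profiles belong to one mitotype;
individuals with no shared SNP at all form singleton mitotypes.  Pooled
sequencing of cyst samples from different years then gives, at every SNP,
an estimate of the population frequency of the lineage carrying it, and the
per-year frequency *envelope* of a mitotype is the frequency of its most
frequent shared SNP (most frequent private SNP for singletons).

Absence of recombination imposes a testable consistency constraint: within
a mitotype, the summed pool frequencies of private SNPs can never exceed
the frequency of the shared SNPs that define the lineage.

Inputs are long-format base-fraction tables (one row per sample, position
and base, with the fraction of reads showing that base and the total
coverage), i.e. the standard per-position output of pileup summarisers,
taken downstream of read mapping.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from skbio import TreeNode

from .errors import SchemaError

log = logging.getLogger("thermoadapt")

BASES = ("A", "C", "G", "T")

#: Reference intervals (1-based, inclusive) dropped from SNP calling.
#: These correspond to assembly regions where short-read coverage
#: collapses and calls are unreliable.
DEFAULT_EXCLUDED_REGIONS: tuple[tuple[int, int], ...] = (
    (14045, 14394),
    (14682, 14835),
    (15409, 15806),
)


@dataclass(frozen=True)
class SampleInfo:
    """Role of one sequenced sample: a single individual or a year-labelled
    pool (optionally one of several replicate extractions)."""

    kind: str  # "individual" | "pool"
    year: int | None = None
    replicate: int = 1

    def __post_init__(self):
        if self.kind not in ("individual", "pool"):
            raise SchemaError(f"sample kind must be individual|pool, got {self.kind!r}")


class BaseFractionTable:
    """Per-(sample, position) base fractions and coverage.

    Parameters
    ----------
    frac
        DataFrame indexed by ``(sample, position)`` with columns
        ``A, C, G, T, coverage``.  Fractions are of reads supporting each
        base; positions are 1-based on the (circular) reference.
    reference_length
        Optional length of the reference; positions must not exceed it.
    excluded_regions
        1-based inclusive intervals ignored during SNP calling.
    samples
        Mapping from sample name to :class:`SampleInfo`.  Samples absent
        from the mapping are treated as individuals.
    """

    def __init__(
        self,
        frac: pd.DataFrame,
        reference_length: int | None = None,
        excluded_regions: tuple[tuple[int, int], ...] = (),
        samples: dict[str, SampleInfo] | None = None,
    ):
        frac = frac.copy()
        frac.index = frac.index.set_names(["sample", "position"])
        missing = [c for c in (*BASES, "coverage") if c not in frac.columns]
        if missing:
            raise SchemaError(f"base-fraction table missing columns: {missing}")
        f = frac[list(BASES)].to_numpy(float)
        if np.any((f < 0) | (f > 1)):
            raise SchemaError("base fractions must lie in [0, 1]")
        sums = f.sum(axis=1)
        if np.any(sums > 1 + 1e-6):
            bad = frac.index[np.argmax(sums)]
            raise SchemaError(f"fractions sum to >1 at (sample, position)={bad}")
        if np.any(frac["coverage"].to_numpy(float) < 0):
            raise SchemaError("coverage must be >= 0")
        pos = frac.index.get_level_values("position")
        if len(pos) and pos.min() < 1:
            raise SchemaError("positions are 1-based; found position < 1")
        if reference_length is not None and len(pos) and pos.max() > reference_length:
            raise SchemaError("position exceeds reference length")
        self.frac = frac.sort_index()
        self.reference_length = reference_length
        self.excluded_regions = tuple(tuple(r) for r in excluded_regions)
        self.samples = dict(samples or {})

    # -- accessors -----------------------------------------------------
    @property
    def sample_names(self) -> list[str]:
        return list(self.frac.index.get_level_values("sample").unique())

    def info(self, sample: str) -> SampleInfo:
        return self.samples.get(sample, SampleInfo("individual"))

    def individual_samples(self) -> list[str]:
        return [s for s in self.sample_names if self.info(s).kind == "individual"]

    def pool_samples(self) -> list[str]:
        return [s for s in self.sample_names if self.info(s).kind == "pool"]

    def pool_years(self) -> list[int]:
        return sorted({self.info(s).year for s in self.pool_samples()})

    def is_excluded(self, position: int) -> bool:
        return any(lo <= position <= hi for lo, hi in self.excluded_regions)

    def fraction(self, sample: str, position: int, base: str) -> float:
        try:
            return float(self.frac.loc[(sample, position), base])
        except KeyError:
            return 0.0

    def equals(self, other: "BaseFractionTable", atol: float = 0.0) -> bool:
        if set(self.frac.index) != set(other.frac.index):
            return False
        a = self.frac.sort_index()
        b = other.frac.reindex(a.index)
        return bool(np.allclose(a.to_numpy(float), b.to_numpy(float), atol=atol, rtol=0))


@dataclass(frozen=True)
class SNPCall:
    """A single-base substitution and the individuals carrying it."""

    position: int
    ref: str
    alt: str
    carriers: frozenset[str]
    klass: str | None = None  # "shared" | "private"

    @property
    def snp_id(self) -> str:
        return f"{self.position}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class Mitotype:
    """A maternal lineage defined by a shared-SNP profile."""

    mitotype_id: str
    members: tuple[str, ...]
    shared_snps: tuple[SNPCall, ...]
    private_snps: tuple[SNPCall, ...]
    singleton: bool


@dataclass
class MitotypeSet:
    mitotypes: list[Mitotype]
    newick: str
    conflicts: list[tuple[SNPCall, SNPCall]] = field(default_factory=list)

    def by_id(self, mitotype_id: str) -> Mitotype:
        return next(m for m in self.mitotypes if m.mitotype_id == mitotype_id)


@dataclass
class FrequencyEnvelope:
    """Per-year upper-bound frequency of one mitotype, with the member
    SNP frequency series retained for inspection."""

    mitotype_id: str
    envelope: dict[int, float]
    shared_series: dict[str, dict[int, float]]
    private_series: dict[str, dict[int, float]]


# ---------------------------------------------------------------------------
# SNP calling and classification
# ---------------------------------------------------------------------------

def call_individual_snps(
    table: BaseFractionTable,
    min_alt_fraction: float = 0.8,
    min_coverage: int = 20,
) -> list[SNPCall]:
    """Call single-base substitutions that distinguish sequenced individuals.

    For each individual and position, the carried base is the majority base
    provided its fraction is at least ``min_alt_fraction`` and coverage is
    at least ``min_coverage`` (mitochondria are effectively homoplasmic, so
    a confident call is near-fixed within an individual).  A position is a
    variant if called individuals disagree; the reference base is the modal
    called base and every other called base yields one :class:`SNPCall`.
    Positions inside excluded regions are dropped.  Only substitutions are
    considered — indels never enter the table representation.
    """
    individuals = table.individual_samples()
    if not individuals:
        return []
    sub = table.frac.loc[table.frac.index.get_level_values("sample").isin(individuals)]
    f = sub[list(BASES)].to_numpy(float)
    cov = sub["coverage"].to_numpy(float)
    best = f.argmax(axis=1)
    ok = (f[np.arange(len(f)), best] >= min_alt_fraction) & (cov >= min_coverage)

    calls_by_pos: dict[int, dict[str, str]] = {}
    low_cov = Counter()
    n_pos = Counter()
    idx_sample = sub.index.get_level_values("sample")
    idx_pos = sub.index.get_level_values("position")
    for i in range(len(sub)):
        s, p = idx_sample[i], int(idx_pos[i])
        n_pos[s] += 1
        if cov[i] < min_coverage:
            low_cov[s] += 1
        if table.is_excluded(p) or not ok[i]:
            continue
        calls_by_pos.setdefault(p, {})[s] = BASES[best[i]]

    for s in individuals:
        if n_pos[s] and low_cov[s] / n_pos[s] > 0.20:
            log.warning(
                "event=low_coverage_individual sample=%s frac_below_floor=%.3f", s,
                low_cov[s] / n_pos[s],
            )

    out: list[SNPCall] = []
    for p in sorted(calls_by_pos):
        by_base = calls_by_pos[p]
        bases = set(by_base.values())
        if len(bases) < 2:
            continue
        counts = Counter(by_base.values())
        top = max(counts.values())
        # modal called base is the reference; ties broken alphabetically
        ref = sorted(b for b, c in counts.items() if c == top)[0]
        for alt in sorted(bases - {ref}):
            carriers = frozenset(s for s, b in by_base.items() if b == alt)
            out.append(SNPCall(p, ref, alt, carriers))
    return out


def classify_shared_private(calls: list[SNPCall]) -> list[SNPCall]:
    """Label each call shared (>= 2 carriers) or private (exactly 1)."""
    if not calls:
        return []
    return [
        SNPCall(c.position, c.ref, c.alt, c.carriers,
                "shared" if len(c.carriers) >= 2 else "private")
        for c in calls
    ]


def shared_private_counts(calls: list[SNPCall]) -> tuple[int, int]:
    ks = [c.klass for c in calls]
    return ks.count("shared"), ks.count("private")


# ---------------------------------------------------------------------------
# Mitotype definition
# ---------------------------------------------------------------------------

def _laminar_conflicts(shared: list[SNPCall]) -> list[tuple[SNPCall, SNPCall]]:
    """Pairs of shared SNPs whose carrier sets overlap partially.

    Without recombination, carrier sets must form a laminar family
    (pairwise nested or disjoint); a partial overlap implies recombination
    or a calling error and is flagged rather than silently merged."""
    bad = []
    for i in range(len(shared)):
        for j in range(i + 1, len(shared)):
            a, b = shared[i].carriers, shared[j].carriers
            inter = a & b
            if inter and not (a <= b or b <= a):
                bad.append((shared[i], shared[j]))
    return bad


def define_mitotypes(calls: list[SNPCall], individuals: list[str]) -> MitotypeSet:
    """Group individuals into mitotypes by their shared-SNP profiles.

    Individuals with identical (non-empty) shared-SNP profiles form one
    mitotype defined by those SNPs; individuals carrying no shared SNP each
    become a singleton mitotype.  Private SNPs are attached to the mitotype
    of their single carrier.  A dendrogram over individuals is built by
    single linkage on the Hamming distance between shared-SNP presence
    profiles; profile-less individuals are therefore grouped as siblings.
    """
    classified = [c for c in calls if c.klass is not None]
    if len(classified) != len(calls):
        classified = classify_shared_private(calls)
    shared = [c for c in classified if c.klass == "shared"]
    private = [c for c in classified if c.klass == "private"]

    conflicts = _laminar_conflicts(shared)
    if conflicts:
        for a, b in conflicts:
            log.warning("event=recombination_like_conflict snp_a=%s snp_b=%s",
                        a.snp_id, b.snp_id)

    profiles: dict[str, frozenset[str]] = {
        ind: frozenset(c.snp_id for c in shared if ind in c.carriers)
        for ind in individuals
    }
    groups: dict[frozenset[str], list[str]] = {}
    for ind in individuals:
        if profiles[ind]:
            groups.setdefault(profiles[ind], []).append(ind)

    mitotypes: list[Mitotype] = []
    ordered = sorted(groups.items(), key=lambda kv: min(individuals.index(m) for m in kv[1]))
    for profile, members in ordered:
        snps = tuple(c for c in shared if c.snp_id in profile)
        priv = tuple(c for c in private if next(iter(c.carriers)) in members)
        mitotypes.append(Mitotype(
            mitotype_id=f"M{len(mitotypes) + 1}",
            members=tuple(sorted(members, key=individuals.index)),
            shared_snps=snps,
            private_snps=priv,
            singleton=False,
        ))
    for ind in individuals:
        if not profiles[ind]:
            priv = tuple(c for c in private if next(iter(c.carriers)) == ind)
            mitotypes.append(Mitotype(
                mitotype_id=f"M{len(mitotypes) + 1}",
                members=(ind,),
                shared_snps=(),
                private_snps=priv,
                singleton=True,
            ))

    newick = _sharing_dendrogram(profiles, shared, individuals)
    return MitotypeSet(mitotypes=mitotypes, newick=newick, conflicts=conflicts)


def _sharing_dendrogram(profiles, shared, individuals) -> str:
    if len(individuals) < 2:
        return f"({individuals[0]});" if individuals else ";"
    snp_ids = [c.snp_id for c in shared]
    if snp_ids:
        X = np.array([[sid in profiles[ind] for sid in snp_ids] for ind in individuals],
                     dtype=float)
        d = pdist(X, metric="hamming")
    else:
        d = np.ones(len(individuals) * (len(individuals) - 1) // 2)
    Z = linkage(d, method="single")
    tree = TreeNode.from_linkage_matrix(Z, individuals)
    return str(tree).strip()


# ---------------------------------------------------------------------------
# Frequency envelopes and the no-recombination check
# ---------------------------------------------------------------------------

def pool_snp_frequency(table: BaseFractionTable, call: SNPCall) -> dict[int, float]:
    """Mean alt-base fraction per year across replicate pools.

    A pool sample lacking the position contributes frequency 0 (logged)."""
    by_year: dict[int, list[float]] = {}
    for s in table.pool_samples():
        year = table.info(s).year
        try:
            val = float(table.frac.loc[(s, call.position), call.alt])
        except KeyError:
            log.info("event=snp_absent_from_pool sample=%s snp=%s treated_as=0",
                     s, call.snp_id)
            val = 0.0
        by_year.setdefault(year, []).append(val)
    return {y: float(np.mean(v)) for y, v in sorted(by_year.items())}


def compute_frequency_envelopes(
    mitotypes: MitotypeSet | list[Mitotype],
    table: BaseFractionTable,
    per_year: bool = True,
) -> list[FrequencyEnvelope]:
    """Per-year envelope frequency of each mitotype from pooled samples.

    The envelope is the maximum over the mitotype's shared-SNP pool
    frequencies (private-SNP frequencies for singletons).  With
    ``per_year=True`` (default) the maximising SNP may differ between
    years, giving the tightest upper envelope; with ``per_year=False`` a
    single SNP — the one with the highest mean frequency across years — is
    used throughout.
    """
    mts = mitotypes.mitotypes if isinstance(mitotypes, MitotypeSet) else mitotypes
    years = table.pool_years()
    out = []
    for m in mts:
        shared_series = {c.snp_id: pool_snp_frequency(table, c) for c in m.shared_snps}
        private_series = {c.snp_id: pool_snp_frequency(table, c) for c in m.private_snps}
        source = private_series if m.singleton else shared_series
        if not source:
            env = {y: 0.0 for y in years}
        elif per_year:
            env = {y: max(series.get(y, 0.0) for series in source.values())
                   for y in years}
        else:
            best = max(source, key=lambda sid: np.mean(list(source[sid].values()) or [0]))
            env = {y: source[best].get(y, 0.0) for y in years}
        out.append(FrequencyEnvelope(m.mitotype_id, env, shared_series, private_series))
    return out


def check_no_recombination_invariant(
    mitotypes: MitotypeSet | list[Mitotype],
    table: BaseFractionTable,
    n_sd: float = 3.0,
) -> pd.DataFrame:
    """Check, per mitotype and year, that summed private-SNP pool
    frequencies do not exceed the maximum shared-SNP pool frequency.

    Returns a tidy frame with the margin (shared max − private sum) and a
    pass flag; the tolerance is ``n_sd`` pooled-binomial standard
    deviations at the year's mean pool coverage.  Mitotypes without shared
    SNPs (singletons) pass trivially and are omitted.
    """
    mts = mitotypes.mitotypes if isinstance(mitotypes, MitotypeSet) else mitotypes
    cov_by_year: dict[int, float] = {}
    for s in table.pool_samples():
        y = table.info(s).year
        cov_by_year.setdefault(y, 0.0)
    for y in cov_by_year:
        samples = [s for s in table.pool_samples() if table.info(s).year == y]
        covs = [table.frac.loc[s]["coverage"].mean() for s in samples]
        cov_by_year[y] = float(np.mean(covs)) if covs else np.inf

    rows = []
    for m in mts:
        if m.singleton or not m.shared_snps:
            continue
        shared = {c.snp_id: pool_snp_frequency(table, c) for c in m.shared_snps}
        private = {c.snp_id: pool_snp_frequency(table, c) for c in m.private_snps}
        for y in table.pool_years():
            smax = max(series.get(y, 0.0) for series in shared.values())
            psum = sum(series.get(y, 0.0) for series in private.values())
            cov = cov_by_year.get(y, np.inf)
            tol = 0.0 if not np.isfinite(cov) or cov <= 0 else \
                n_sd * np.sqrt(max(smax * (1 - smax), 1e-12) / cov)
            margin = smax - psum
            rows.append({
                "mitotype": m.mitotype_id, "year": y,
                "shared_max": smax, "private_sum": psum,
                "margin": margin, "tolerance": tol,
                "passed": margin >= -tol,
            })
    return pd.DataFrame(rows, columns=[
        "mitotype", "year", "shared_max", "private_sum", "margin", "tolerance", "passed",
    ])


def replicate_concordance(freqs_a, freqs_b) -> float:
    """Squared Pearson correlation between matched per-SNP pool
    frequency vectors from two replicate extractions of one year."""
    a = np.asarray(freqs_a, float)
    b = np.asarray(freqs_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise SchemaError("replicate frequency vectors must be matched 1-d arrays")
    if len(a) < 3:
        raise SchemaError("need >= 3 matched SNPs for a concordance estimate")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise SchemaError("zero variance in a replicate frequency vector")
    r = pearsonr(a, b).statistic
    return float(r * r)
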