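import numpy as np
import pandas as pd
import pytest

from thermoadapt.simulate import EffectSpec, ExperimentDesign

FACTOR_DEFAULTS = {
    "experiment": "additive", "regime": "T_VCH", "population": "SFB84",
    "cross_status": "own", "clutch": "NA", "parental_treatment": "NA",
    "phase1_regime": "NA", "microbiome": "NA", "family_id": "NA",
}


def survival_rows(rows):
    """Build a full survival frame from partial row dicts."""
    out = []
    for i, r in enumerate(rows):
        rec = {**FACTOR_DEFAULTS, "tube_id": f"t{i:05d}", "n_total": 10,
               "n_alive": 5, **r}
        out.append(rec)
    return pd.DataFrame(out)


def two_pop_family_design(n_families=60, tubes_per_family=4, n_per_tube=10,
                          populations=("SFB84", "VCH08")):
    """Two populations, families nested in population, several tubes per
    family — the workhorse layout for parameter-recovery simulations."""
    rows = []
    per_pop = n_families // len(populations)
    for pop in populations:
        for f in range(per_pop):
            for t in range(tubes_per_family):
                rows.append({
                    **FACTOR_DEFAULTS, "experiment": "parental",
                    "population": pop, "family_id": f"{pop}-F{f:03d}",
                    "tube_id": f"{pop}-F{f:03d}-T{t}", "n_total": n_per_tube,
                    "n_alive": 0,
                })
    return ExperimentDesign("parental", pd.DataFrame(rows))


def pop_effect_spec(shift=1.0, sigma_family=0.0, sigma_obs=0.0, baseline=0.0,
                    population="VCH08"):
    return EffectSpec.build(
        baseline_logit=baseline,
        effects=[({"population": population}, shift)],
        sigma_family=sigma_family, sigma_obs=sigma_obs,
    )


def independent_binomial_loglik(beta, X, y, n):
    """Independent oracle: plain binomial-logit log-likelihood."""
    from scipy.special import gammaln
    eta = X @ beta
    lchoose = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return float(np.sum(lchoose + y * eta - n * np.logaddexp(0, eta)))


@pytest.fixture(scope="session")
def study_mito_tables():
    """Noiseless synthetic dataset with the study's mitotype structure."""
    from thermoadapt.simulate import simulate_mito_dataset, study_mitotype_population
    pop = study_mitotype_population()
    geno, table = simulate_mito_dataset(
        pop, error_rate=0.0, analytic=True, seed=0,
        replicate_years=(1984, 1997, 2008))
    return pop, geno, table
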