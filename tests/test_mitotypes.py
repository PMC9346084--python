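"""SNP calling, mitotype definition, envelopes, no-recombination check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thermoadapt.errors import SchemaError
from thermoadapt.mitotypes import (BASES, BaseFractionTable,
                                   DEFAULT_EXCLUDED_REGIONS, SampleInfo,
                                   call_individual_snps,
                                   check_no_recombination_invariant,
                                   classify_shared_private,
                                   compute_frequency_envelopes,
                                   define_mitotypes, replicate_concordance,
                                   shared_private_counts)
from thermoadapt.simulate import (random_mitotype_population,
                                  simulate_mito_dataset)


def make_table(entries, samples=None, excluded=(), ref_len=None):
    """entries: (sample, position, {base: fraction}, coverage)"""
    rows = []
    for sample, pos, fracs, cov in entries:
        rec = {b: fracs.get(b, 0.0) for b in BASES}
        rows.append({"sample": sample, "position": pos, **rec, "coverage": cov})
    frac = pd.DataFrame(rows).set_index(["sample", "position"])
    return BaseFractionTable(frac, reference_length=ref_len,
                             excluded_regions=excluded, samples=samples)


def run_pipeline(table):
    calls = classify_shared_private(call_individual_snps(table))
    mts = define_mitotypes(calls, table.individual_samples())
    return calls, mts


class TestSNPCalling:
    def test_reference_matching_samples_yield_no_calls(self):
        table = make_table([(s, p, {"A": 1.0}, 100)
                            for s in ("i1", "i2") for p in (10, 20, 30)])
        assert call_individual_snps(table) == []

    def test_toy_threshold_rule_single_call(self):
        entries = []
        for p in (10, 20, 30):
            entries.append(("i1", p, {"A": 1.0}, 100))
            if p == 20:
                entries.append(("i2", p, {"G": 0.9, "A": 0.1}, 100))
            else:
                entries.append(("i2", p, {"A": 1.0}, 100))
        calls = call_individual_snps(make_table(entries))
        assert len(calls) == 1
        (c,) = calls
        assert (c.position, c.ref, c.alt, c.carriers) == (20, "A", "G",
                                                          frozenset({"i2"}))

    def test_low_fraction_or_coverage_suppresses_call(self):
        entries = [("i1", 10, {"A": 1.0}, 100),
                   ("i2", 10, {"G": 0.7, "A": 0.3}, 100),   # below 0.8
                   ("i1", 20, {"A": 1.0}, 100),
                   ("i2", 20, {"G": 1.0}, 10)]              # below coverage 20
        assert call_individual_snps(make_table(entries)) == []

    def test_excluded_region_drops_variant(self):
        entries = [("i1", 14100, {"A": 1.0}, 100),
                   ("i2", 14100, {"G": 1.0}, 100),
                   ("i1", 500, {"C": 1.0}, 100),
                   ("i2", 500, {"T": 1.0}, 100)]
        calls = call_individual_snps(
            make_table(entries, excluded=DEFAULT_EXCLUDED_REGIONS))
        assert [c.position for c in calls] == [500]

    def test_pool_samples_do_not_contribute_to_calling(self):
        samples = {"i1": SampleInfo("individual"),
                   "p84": SampleInfo("pool", 1984)}
        entries = [("i1", 10, {"A": 1.0}, 100), ("p84", 10, {"G": 1.0}, 3000)]
        assert call_individual_snps(make_table(entries, samples=samples)) == []


class TestClassification:
    def test_single_individual_dataset_is_all_private(self):
        entries = [("i1", p, {"G": 1.0}, 100) for p in (10, 20)]
        # a lone individual never disagrees with the consensus: no calls
        assert call_individual_snps(make_table(entries)) == []

    def test_shared_vs_private_rule(self):
        entries = []
        for ind in ("i1", "i2", "i3", "i4", "i5"):
            entries.append((ind, 10, {"G" if ind in ("i1", "i2") else "A": 1.0}, 100))
            entries.append((ind, 20, {"T" if ind == "i3" else "A": 1.0}, 100))
        calls = classify_shared_private(call_individual_snps(make_table(entries)))
        by_pos = {c.position: c for c in calls}
        assert by_pos[10].klass == "shared" and by_pos[10].carriers == {"i1", "i2"}
        assert by_pos[20].klass == "private" and by_pos[20].carriers == {"i3"}

    def test_study_structure_counts(self, study_mito_tables):
        _, _, table = study_mito_tables
        calls = classify_shared_private(call_individual_snps(table))
        assert shared_private_counts(calls) == (7, 32)


class TestMitotypeDefinition:
    def test_no_shared_snps_gives_all_singletons(self):
        entries = []
        for k, ind in enumerate(("i1", "i2", "i3", "i4")):
            for p in (10, 20, 30, 40):
                base = "G" if p == (k + 1) * 10 else "A"
                entries.append((ind, p, {base: 1.0}, 100))
        _, mts = run_pipeline(make_table(entries))
        assert len(mts.mitotypes) == 4
        assert all(m.singleton for m in mts.mitotypes)

    def test_study_sharing_pattern_gives_six_mitotypes(self, study_mito_tables):
        pop, _, table = study_mito_tables
        _, mts = run_pipeline(table)
        assert len(mts.mitotypes) == 6
        parts = {frozenset(m.members) for m in mts.mitotypes}
        assert parts == {frozenset(s) for s in (
            {"ind07", "ind10"}, {"ind05", "ind06"}, {"ind02", "ind04", "ind08"},
            {"ind01"}, {"ind03"}, {"ind09"})}
        assert not mts.conflicts
        # singletons are grouped as dendrogram siblings
        assert "ind01" in mts.newick and mts.newick.endswith(";")

    def test_nested_sharing_pattern(self):
        # SNP alpha carried by i1,i2,i3; beta by i1,i2 only -> two mitotypes
        entries = []
        for ind in ("i1", "i2", "i3", "i4", "i5", "i6", "i7"):
            entries.append((ind, 10, {"G" if ind in ("i1", "i2", "i3") else "A": 1.0}, 100))
            entries.append((ind, 20, {"T" if ind in ("i1", "i2") else "C": 1.0}, 100))
        _, mts = run_pipeline(make_table(entries))
        parts = {frozenset(m.members) for m in mts.mitotypes if not m.singleton}
        assert parts == {frozenset({"i1", "i2"}), frozenset({"i3"})}
        assert not mts.conflicts

    def test_partial_overlap_is_flagged_as_conflict(self):
        # alpha in {i1,i2}, beta in {i2,i3}: laminarity violated
        entries = []
        for ind in ("i1", "i2", "i3", "i4", "i5"):
            entries.append((ind, 10, {"G" if ind in ("i1", "i2") else "A": 1.0}, 100))
            entries.append((ind, 20, {"T" if ind in ("i2", "i3") else "C": 1.0}, 100))
        _, mts = run_pipeline(make_table(entries))
        assert len(mts.conflicts) == 1


class TestEnvelopes:
    def _pool_table(self, shared_fracs_by_year):
        inds = ("i1", "i2", "i3", "i4", "i5")
        samples = {i: SampleInfo("individual") for i in inds}
        entries = []
        for ind in inds:
            for p in (10, 20):
                carrier = ind in ("i1", "i2")
                base = {10: "G", 20: "T"}[p] if carrier else "A"
                entries.append((ind, p, {base: 1.0}, 100))
        for year, (f10, f20) in shared_fracs_by_year.items():
            s = f"pool{year}"
            samples[s] = SampleInfo("pool", year)
            entries.append((s, 10, {"G": f10, "A": 1 - f10}, 3000))
            entries.append((s, 20, {"T": f20, "A": 1 - f20}, 3000))
        return make_table(entries, samples=samples)

    def test_single_snp_envelope_is_its_frequency(self):
        table = self._pool_table({1984: (0.22, 0.22)})
        _, mts = run_pipeline(table)
        envs = compute_frequency_envelopes(mts, table)
        env = next(e for e in envs if e.shared_series)
        assert env.envelope[1984] == pytest.approx(0.22)

    def test_envelope_takes_per_year_maximum(self):
        table = self._pool_table({1984: (0.12, 0.15), 1997: (0.30, 0.18)})
        _, mts = run_pipeline(table)
        env = next(e for e in compute_frequency_envelopes(mts, table)
                   if e.shared_series)
        assert env.envelope[1984] == pytest.approx(0.15)
        assert env.envelope[1997] == pytest.approx(0.30)

    def test_global_argmax_option_uses_one_snp_throughout(self):
        table = self._pool_table({1984: (0.12, 0.15), 1997: (0.30, 0.18)})
        _, mts = run_pipeline(table)
        env = next(e for e in compute_frequency_envelopes(mts, table,
                                                          per_year=False)
                   if e.shared_series)
        # position 10 has the higher mean frequency -> used in both years
        assert env.envelope[1984] == pytest.approx(0.12)
        assert env.envelope[1997] == pytest.approx(0.30)

    def test_adding_a_shared_snp_never_lowers_the_envelope(self):
        one = self._pool_table({1984: (0.12, 0.0)})
        both = self._pool_table({1984: (0.12, 0.25)})
        env1 = next(e for e in compute_frequency_envelopes(*(
            run_pipeline(one)[1], one)) if e.shared_series)
        env2 = next(e for e in compute_frequency_envelopes(*(
            run_pipeline(both)[1], both)) if e.shared_series)
        assert env2.envelope[1984] >= env1.envelope[1984]


class TestNoRecombinationInvariant:
    def test_constructed_violation_reports_negative_margin(self):
        inds = ("i1", "i2", "i3", "i4", "i5")
        samples = {i: SampleInfo("individual") for i in inds}
        samples["pool1984"] = SampleInfo("pool", 1984)
        entries = []
        for ind in inds:
            entries.append((ind, 10, {"G" if ind in ("i1", "i2") else "A": 1.0}, 100))
            entries.append((ind, 20, {"T" if ind == "i1" else "C": 1.0}, 100))
        entries.append(("pool1984", 10, {"G": 0.2, "A": 0.8}, 3000))
        entries.append(("pool1984", 20, {"T": 0.3, "C": 0.7}, 3000))
        table = make_table(entries, samples=samples)
        _, mts = run_pipeline(table)
        report = check_no_recombination_invariant(mts, table)
        row = report.iloc[0]
        assert row["margin"] == pytest.approx(-0.1)
        assert not row["passed"]

    def test_mitotype_without_private_snps_passes(self, study_mito_tables):
        _, _, table = study_mito_tables
        _, mts = run_pipeline(table)
        report = check_no_recombination_invariant(mts, table)
        assert report["passed"].all()
        assert (report["margin"] >= 0).all()


class TestReplicateConcordance:
    def test_identical_vectors(self):
        assert replicate_concordance([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == \
            pytest.approx(1.0)

    def test_hand_computed_r_squared(self):
        x, y = [0.1, 0.2, 0.3], [0.1, 0.25, 0.3]
        r = np.corrcoef(x, y)[0, 1]
        assert replicate_concordance(x, y) == pytest.approx(r * r, abs=1e-12)
        assert replicate_concordance(x, y) == pytest.approx(0.923, abs=5e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(SchemaError):
            replicate_concordance([0.1, 0.2], [0.1, 0.2])
        with pytest.raises(SchemaError, match="variance"):
            replicate_concordance([0.1, 0.1, 0.1], [0.1, 0.2, 0.3])

    def test_simulated_replicates_highly_concordant_at_study_coverage(self):
        from thermoadapt.simulate import study_mitotype_population
        pop = study_mitotype_population()
        _, table = simulate_mito_dataset(pop, mean_coverage=3000,
                                         error_rate=0.001, seed=2,
                                         replicate_years=(1984,))
        snps = pop.all_snps()
        a = [table.fraction("pool1984", s.position, s.alt) for s in snps]
        b = [table.fraction("pool1984r2", s.position, s.alt) for s in snps]
        assert replicate_concordance(a, b) > 0.98


class TestExactRecoveryProperty:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           n_multi=st.integers(1, 3), n_singletons=st.integers(1, 3))
    def test_noiseless_pipeline_recovers_truth_exactly(self, seed, n_multi,
                                                       n_singletons):
        pop = random_mitotype_population(seed=seed, n_multi=n_multi,
                                         n_singletons=n_singletons)
        assert len(pop.individuals) <= 12 and len(pop.all_snps()) <= 60
        geno, table = simulate_mito_dataset(pop, error_rate=0.0, analytic=True)
        calls, mts = run_pipeline(table)
        # partition
        truth = {frozenset(m.individual_id for m in lin.members)
                 for lin in pop.lineages}
        assert {frozenset(m.members) for m in mts.mitotypes} == truth
        # shared/private split
        n_shared = sum(len(lin.shared_snps) for lin in pop.lineages)
        n_private = sum(len(m.private_snps) for m in pop.individuals)
        assert shared_private_counts(calls) == (n_shared, n_private)
        # envelopes equal true lineage frequencies
        lineage_of = {frozenset(m.individual_id for m in lin.members): lin
                      for lin in pop.lineages}
        for env in compute_frequency_envelopes(mts, table):
            members = frozenset(mts.by_id(env.mitotype_id).members)
            lin = lineage_of[members]
            for year in pop.years:
                assert env.envelope[year] == pytest.approx(
                    lin.frequencies[year], abs=1e-12)
        # no-recombination margins non-negative
        report = check_no_recombination_invariant(mts, table)
        if len(report):
            assert (report["margin"] >= -1e-12).all()

    def test_envelope_error_shrinks_with_coverage(self):
        errs = []
        for cov in (100, 1000, 10_000):
            diffs = []
            for seed in range(8):
                pop = random_mitotype_population(seed=seed)
                _, table = simulate_mito_dataset(pop, mean_coverage=cov,
                                                 error_rate=0.0, seed=seed + 99)
                _, mts = run_pipeline(table)
                lineage_of = {frozenset(m.individual_id for m in lin.members): lin
                              for lin in pop.lineages}
                for env in compute_frequency_envelopes(mts, table):
                    lin = lineage_of[frozenset(mts.by_id(env.mitotype_id).members)]
                    diffs.extend(abs(env.envelope[y] - lin.frequencies[y])
                                 for y in pop.years)
            errs.append(np.mean(diffs))
        assert errs[0] > errs[1] > errs[2]
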