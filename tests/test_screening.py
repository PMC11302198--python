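import numpy as np
import pytest
from scipy import stats

from stroopsense import (
    BundleMap,
    PairwiseRatioMatrix,
    bundle_tests,
    demographic_comparison,
    ks_between_group_ratio,
    pairwise_within_group_ratio,
)
from stroopsense.cohort import ParticipantRecord
from stroopsense.errors import (
    InsufficientSampleError,
    InvalidParameterError,
    MissingBundleError,
)
from .conftest import make_table


def _two_type_table(rng, n_per_group=12, n_feat=10, type_gap=3.0, noise=1.0):
    """Four tests in two types (A1, A2 / B1, B2); same-type tests exchangeable."""
    tests = ["A1", "A2", "B1", "B2"]
    participants = [f"p{i}" for i in range(2 * n_per_group)]
    groups = ["CG"] * n_per_group + ["EG"] * n_per_group
    shift_b = rng.normal(0, type_gap, n_feat)
    values = []
    for i in range(2 * n_per_group):
        subj = rng.normal(0, 0.5)
        for t in tests:
            base = shift_b if t.startswith("B") else 0.0
            values.append(base + subj + rng.normal(0, noise, n_feat))
    mods = {"EDA": [f"EDA_f{j+1}" for j in range(n_feat // 2)],
            "HRV": [f"HRV_f{j+1}" for j in range(n_feat - n_feat // 2)]}
    names = mods["EDA"] + mods["HRV"]
    mods = {"EDA": names[: n_feat // 2], "HRV": names[n_feat // 2 :]}
    return make_table(values, mods, participants, tests, groups)


@pytest.fixture(scope="module")
def table():
    return _two_type_table(np.random.default_rng(11))


class TestPairwiseWilcoxon:

    def test_matrix_invariants(self, table):
        m = pairwise_within_group_ratio(table, "CG")
        assert np.all(np.diag(m.ratios) == 0)
        assert np.allclose(m.ratios, m.ratios.T)
        assert np.all((m.ratios >= 0) & (m.ratios <= 1))

    def test_cross_type_exceeds_same_type(self, table):
        for group in ("CG", "EG"):
            m = pairwise_within_group_ratio(table, group).as_frame()
            same = [m.loc["A1", "A2"], m.loc["B1", "B2"]]
            cross = [m.loc["A1", "B1"], m.loc["A2", "B2"], m.loc["A1", "B2"]]
            assert max(same) < min(cross)

    def test_identical_tests_ratio_zero(self):
        """Two tests with identical values for every participant give ratio 0."""
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(8, 4))
        values = np.repeat(vals, 2, axis=0)  # T1 row == T2 row per participant
        table = make_table(
            values,
            {"EDA": [f"EDA_f{j+1}" for j in range(4)]},
            [f"p{i}" for i in range(8)],
            ["T1", "T2"],
            ["CG"] * 8,
        )
        m = pairwise_within_group_ratio(table, "CG")
        assert m.ratios[0, 1] == 0.0

    def test_positive_affine_invariance(self, table):
        """The signed-rank test ranks paired differences, so any positive
        affine rescaling of a feature (units change) leaves the matrix fixed.
        Arbitrary monotone transforms do NOT preserve the signed-rank test
        (they reorder difference magnitudes), so affine is the right check."""
        before = pairwise_within_group_ratio(table, "CG").ratios
        warped = table.data.copy()
        f = table.feature_names[0]
        warped[f] = 3.7 * warped[f] + 11.0
        table2 = type(table)(warped, table.modalities)
        after = pairwise_within_group_ratio(table2, "CG").ratios
        assert np.array_equal(before, after)

    def test_ks_monotone_transform_invariance(self, table):
        """The KS statistic depends only on the two empirical CDFs, so a
        strictly monotone transform applied to a feature across all rows
        leaves the between-group ratios unchanged."""
        bundles = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        before = ks_between_group_ratio(table, bundles).overall
        warped = table.data.copy()
        f = table.feature_names[0]
        warped[f] = np.exp(warped[f])
        after = ks_between_group_ratio(type(table)(warped, table.modalities), bundles).overall
        assert before == after

    def test_too_few_participants_raises(self):
        rng = np.random.default_rng(1)
        table = make_table(
            rng.normal(size=(6, 3)),
            {"EDA": ["EDA_f1", "EDA_f2", "EDA_f3"]},
            ["p0", "p1", "p2"],
            ["T1", "T2"],
            ["CG"] * 3,
        )
        with pytest.raises(InsufficientSampleError):
            pairwise_within_group_ratio(table, "CG")


def _ratio_matrix(labels, same, cross, types):
    n = len(labels)
    r = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r[i, j] = r[j, i] = same if types[labels[i]] == types[labels[j]] else cross
    return PairwiseRatioMatrix(group="CG", test_labels=list(labels), ratios=r, alpha=0.1)


class TestBundling:
    TYPES = {"C1": "C", "C2": "C", "C3": "C", "N-S": "N", "N-V": "N", "E": "E"}
    LABELS = ["C1", "C2", "C3", "N-S", "N-V", "E"]

    def test_study_like_matrices_recover_cne(self):
        cg = _ratio_matrix(self.LABELS, 0.05, 0.5, self.TYPES)
        eg = _ratio_matrix(self.LABELS, 0.05, 0.5, self.TYPES)
        bm = bundle_tests(cg, eg, tau=0.2)
        assert bm.mapping == {
            "C1": "C", "C2": "C", "C3": "C", "N-S": "N", "N-V": "N", "E": "E"
        }

    def test_tau_zero_identity(self):
        cg = _ratio_matrix(self.LABELS, 0.05, 0.5, self.TYPES)
        bm = bundle_tests(cg, cg, tau=0.0)
        assert all(bm.mapping[t] == t for t in self.LABELS)

    def test_edge_requires_both_groups(self):
        cg = _ratio_matrix(self.LABELS, 0.05, 0.5, self.TYPES)
        eg = _ratio_matrix(self.LABELS, 0.5, 0.5, self.TYPES)  # EG never below tau
        bm = bundle_tests(cg, eg, tau=0.2)
        assert all(bm.mapping[t] == t for t in self.LABELS)

    @pytest.mark.parametrize("perm_seed", range(4))
    def test_label_order_invariance(self, perm_seed):
        rng = np.random.default_rng(perm_seed)
        order = rng.permutation(len(self.LABELS))
        labels = [self.LABELS[i] for i in order]
        cg = _ratio_matrix(labels, 0.05, 0.5, self.TYPES)
        bm = bundle_tests(cg, cg, tau=0.2)
        grouping = {frozenset(bm.members(b)) for b in bm.bundles}
        assert grouping == {
            frozenset({"C1", "C2", "C3"}),
            frozenset({"N-S", "N-V"}),
            frozenset({"E"}),
        }

    def test_invalid_tau_raises(self):
        cg = _ratio_matrix(self.LABELS, 0.05, 0.5, self.TYPES)
        with pytest.raises(InvalidParameterError):
            bundle_tests(cg, cg, tau=1.5)


class TestKSBetweenGroups:
    def test_equal_samples_ratio_zero(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(10, 6))
        values = np.vstack([vals, vals])  # EG rows literally equal CG rows
        table = make_table(
            values,
            {"EDA": [f"EDA_f{j+1}" for j in range(6)]},
            [f"p{i}" for i in range(20)],
            ["T1"],
            ["CG"] * 10 + ["EG"] * 10,
        )
        report = ks_between_group_ratio(table, {"T1": "T"})
        assert report.overall["T"] == 0.0

    def test_overall_is_weighted_mean_of_modalities(self):
        table = _two_type_table(np.random.default_rng(3))
        report = ks_between_group_ratio(table, {"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        for bundle, overall in report.overall.items():
            weighted = sum(
                report.per_modality[bundle][m] * len(names)
                for m, names in table.modalities.items()
            ) / len(table.feature_names)
            assert overall == pytest.approx(weighted, abs=1e-12)

    def test_ratio_monotone_in_alpha_and_zero_at_zero(self):
        table = _two_type_table(np.random.default_rng(4))
        bundles = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        prev = ks_between_group_ratio(table, bundles, alpha=0.0)
        assert all(v == 0.0 for v in prev.overall.values())
        last = {b: 0.0 for b in prev.overall}
        for alpha in (0.05, 0.1, 0.5, 1.0):
            rep = ks_between_group_ratio(table, bundles, alpha=alpha)
            assert all(rep.overall[b] >= last[b] for b in last)
            last = rep.overall

    def test_missing_bundle_raises(self):
        table = _two_type_table(np.random.default_rng(5))
        with pytest.raises(MissingBundleError):
            ks_between_group_ratio(table, {"A1": "A", "A2": "A", "Z9": "Z"})

    def test_selected_bundle_attains_max(self, small_cohort):
        _, table = small_cohort
        report = ks_between_group_ratio(
            table, {"C1": "C", "C2": "C", "C3": "C", "N-S": "N", "N-V": "N", "E": "E"}
        )
        assert report.overall[report.selected_bundle] == max(report.overall.values())


def _records(ages_cg, ages_eg, genders_cg, genders_eg):
    recs = []
    for i, (a, g) in enumerate(zip(ages_cg, genders_cg)):
        recs.append(ParticipantRecord(f"c{i}", "CG", a, g, True, True))
    for i, (a, g) in enumerate(zip(ages_eg, genders_eg)):
        recs.append(ParticipantRecord(f"e{i}", "EG", a, g, True, True))
    return recs


class TestDemographics:
    def test_printed_gender_table_chi_square(self):
        """32 M / 26 F controls vs 24 M / 13 F cases: Yates chi-square 0.5221, df 1."""
        recs = _records(
            np.linspace(20, 60, 58),
            np.linspace(20, 60, 37),
            ["M"] * 32 + ["F"] * 26,
            ["M"] * 24 + ["F"] * 13,
        )
        s = demographic_comparison(recs)
        assert s.chi2_statistic == pytest.approx(0.5221, abs=5e-5)
        assert s.chi2_df == 1
        assert s.chi2_n == 95
        assert s.t_df == 93

    def test_identical_ages_t_zero(self):
        ages = np.linspace(20, 50, 20)
        recs = _records(ages, ages, ["M"] * 20, ["F"] * 20)
        s = demographic_comparison(recs)
        assert s.t_statistic == pytest.approx(0.0, abs=1e-12)

    def test_pooled_variance_formula_oracle(self):
        rng = np.random.default_rng(9)
        a1 = rng.normal(35, 10, 30)
        a2 = rng.normal(32, 11, 25)
        recs = _records(a1, a2, ["M"] * 30, ["F"] * 25)
        s = demographic_comparison(recs)
        # direct evaluation of the pooled-variance two-sample t statistic
        n1, n2 = len(a1), len(a2)
        sp2 = ((n1 - 1) * np.var(a1, ddof=1) + (n2 - 1) * np.var(a2, ddof=1)) / (n1 + n2 - 2)
        t = (np.mean(a1) - np.mean(a2)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert s.t_statistic == pytest.approx(t, abs=1e-12)
        assert s.t_pvalue == pytest.approx(2 * stats.t.sf(abs(t), n1 + n2 - 2), abs=1e-12)

    def test_tiny_group_raises(self):
        recs = _records([30.0], np.linspace(20, 40, 5), ["M"], ["F"] * 5)
        with pytest.raises(InsufficientSampleError):
            demographic_comparison(recs)
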