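import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from synthqc.cohort_table import Cohort, CohortSchema, VariableSpec
from synthqc.fidelity import (
    compare_descriptives,
    correlation_matrix,
    discriminator_auc,
    kl_divergence,
    ks_pvalue,
    pcd_from_matrices,
    pcd_l1,
    umap_coverage,
)


def _numeric_cohort(columns: dict, label="real") -> Cohort:
    schema = CohortSchema([VariableSpec(n, "numeric") for n in columns])
    return Cohort(schema, pd.DataFrame({k: pd.Series(v, dtype=float)
                                        for k, v in columns.items()}), label)


class TestKs:
    def test_identical_samples_p_one(self):
        x = np.arange(1.0, 101.0)
        assert ks_pvalue(x, x) == 1.0

    def test_disjoint_supports_tiny_p(self):
        assert ks_pvalue(np.arange(1.0, 101.0), np.arange(1001.0, 1101.0)) < 1e-6

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(50), rng.standard_normal(60)
        assert ks_pvalue(a, b) == ks_pvalue(b, a)

    def test_insufficient_data_raises(self):
        with pytest.raises(ValueError):
            ks_pvalue([1.0], [1.0, 2.0])

    def test_type_one_error_calibration(self):
        """Same-distribution splits should rarely reject at alpha=0.05."""
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            z = rng.standard_normal(2000)
            hits += ks_pvalue(z[:1000], z[1000:]) > 0.05
        assert hits / n_rep >= 0.94


class TestKl:
    def test_identical_counts_zero_raw(self):
        a = ["x"] * 5 + ["y"] * 5
        assert kl_divergence(a, list(a), alpha=0.0) == 0.0

    def test_textbook_value(self):
        # P=(0.5,0.5) vs Q=(0.25,0.75): 0.5*ln2 + 0.5*ln(2/3)
        real = ["a"] * 2 + ["b"] * 2
        syn = ["a"] * 1 + ["b"] * 3
        expected = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)
        assert kl_divergence(real, syn, alpha=0.0) == pytest.approx(expected,
                                                                    abs=1e-12)

    def test_unseen_level_finite_with_smoothing(self):
        v = kl_divergence(["a", "b"], ["b", "b"], alpha=0.5)
        assert math.isfinite(v)

    def test_unseen_level_infinite_without_smoothing(self):
        assert kl_divergence(["a", "b"], ["b", "b"], alpha=0.0) == float("inf")

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            kl_divergence([], ["a"])

    @given(
        st.lists(st.sampled_from("abc"), min_size=1, max_size=30),
        st.lists(st.sampled_from("abc"), min_size=1, max_size=30),
    )
    def test_nonnegative(self, a, b):
        assert kl_divergence(a, b, alpha=0.5) >= -1e-15


class TestCorrelation:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        c = _numeric_cohort({"x": x, "y": 2 * x})
        m = correlation_matrix(c)
        assert m.loc["x", "y"] == pytest.approx(1.0)

    def test_independent_columns_small_r(self):
        rng = np.random.default_rng(2)
        c = _numeric_cohort({"x": rng.standard_normal(10000),
                             "y": rng.standard_normal(10000)})
        assert abs(correlation_matrix(c).loc["x", "y"]) < 0.05

    def test_pairwise_complete_matches_bruteforce(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, np.nan, 3.0, 5.0, 4.0, 7.0])
        c = _numeric_cohort({"x": x, "y": y})
        got = correlation_matrix(c).loc["x", "y"]
        ok = ~np.isnan(x) & ~np.isnan(y)
        expected = np.corrcoef(x[ok], y[ok])[0, 1]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_bruteforce_oracle_full_matrix(self):
        rng = np.random.default_rng(3)
        cols = {f"v{i}": rng.standard_normal(40) for i in range(4)}
        c = _numeric_cohort(cols)
        m = correlation_matrix(c)
        for a in cols:
            for b in cols:
                expected = np.corrcoef(cols[a], cols[b])[0, 1]
                assert m.loc[a, b] == pytest.approx(expected, abs=1e-12)


class TestPcd:
    def test_exact_copy_zero(self, epad_clean):
        assert pcd_l1(epad_clean, epad_clean.copy()) == 0.0

    def test_mean_of_entry_differences(self):
        names = ["a", "b", "c"]
        r = pd.DataFrame([[1.0, 0.5, 0.2], [0.5, 1.0, 0.0], [0.2, 0.0, 1.0]],
                         index=names, columns=names)
        s = pd.DataFrame([[1.0, 0.4, 0.3], [0.4, 1.0, 0.1], [0.3, 0.1, 1.0]],
                         index=names, columns=names)
        assert pcd_from_matrices(r, s) == pytest.approx(0.1, abs=1e-12)
        assert pcd_from_matrices(r, s, reduce="sum") == pytest.approx(0.3, abs=1e-12)

    def test_symmetry(self, epad_clean):
        from synthqc.fixtures import generate_toy_pair

        real, syn = generate_toy_pair("decorrelated", n=300, seed=4)
        assert pcd_l1(real, syn) == pytest.approx(pcd_l1(syn, real), abs=1e-12)

    def test_permutation_raises_pcd_to_mean_abs_offdiag(self):
        from synthqc.fixtures import generate_toy_pair

        real, syn = generate_toy_pair("decorrelated", n=2000, seed=5)
        pcd = pcd_l1(real, syn)
        m = correlation_matrix(real).to_numpy()
        iu = np.triu_indices_from(m, k=1)
        target = float(np.abs(m[iu]).mean())
        assert pcd == pytest.approx(target, rel=0.2)

    def test_schema_mismatch_error(self, epad_clean):
        other = _numeric_cohort({"zzz": np.arange(5.0), "w": np.arange(5.0)})
        with pytest.raises(ValueError, match="schema"):
            pcd_l1(epad_clean, other)


class TestDiscriminator:
    def test_exact_copy_indistinguishable(self, epad_clean):
        res = discriminator_auc(epad_clean, epad_clean.copy(label="synthetic"),
                                n_repeats=3, seed=5)
        assert res.auc_mean == pytest.approx(0.5, abs=0.05)

    def test_constructed_separable_pair(self):
        rng = np.random.default_rng(6)
        r = _numeric_cohort({"flag": np.zeros(200), "x": rng.standard_normal(200)})
        s = _numeric_cohort({"flag": np.ones(200), "x": rng.standard_normal(200)},
                            label="synthetic")
        res = discriminator_auc(r, s, n_repeats=3, seed=6)
        assert res.auc_mean > 0.99

    def test_reports_mean_and_sd_over_repeats(self, epad_clean):
        from synthqc.synthesizer import fit_synthesizer, sample_synthetic

        m = fit_synthesizer(epad_clean, seed=0)
        syn = sample_synthetic(m, epad_clean.n_records, seed=1)
        res = discriminator_auc(epad_clean, syn, n_repeats=10, seed=7)
        assert len(res.aucs) == 10
        assert res.auc_sd > 0

    def test_folds_exceeding_class_size_raise(self):
        r = _numeric_cohort({"x": np.arange(3.0)})
        s = _numeric_cohort({"x": np.arange(3.0)}, label="synthetic")
        with pytest.raises(ValueError, match="n_folds"):
            discriminator_auc(r, s, n_folds=5)


class TestUmapCoverage:
    def test_copy_full_coverage(self):
        rng = np.random.default_rng(7)
        c = _numeric_cohort({"x": rng.standard_normal(300),
                             "y": rng.standard_normal(300),
                             "z": rng.standard_normal(300)})
        cov = umap_coverage(c, c.copy(label="synthetic"), n_neighbors=25, seed=8)
        assert cov.coverage == 1.0

    def test_missing_cluster_detected(self):
        rng = np.random.default_rng(8)
        # two well-separated clusters in the real data
        n = 150
        a = rng.standard_normal((n, 3))
        b = rng.standard_normal((n, 3)) + 25.0
        real = _numeric_cohort({f"v{i}": np.concatenate([a[:, i], b[:, i]])
                                for i in range(3)})
        # synthetic covers only the first cluster
        syn = _numeric_cohort({f"v{i}": np.concatenate([a[:, i], a[:, i]])
                               for i in range(3)}, label="synthetic")
        cov = umap_coverage(real, syn, n_neighbors=25, seed=9)
        assert 0.0 < cov.coverage < 1.0
        assert len(cov.uncovered_cells) > 0

    def test_too_few_records_raise(self):
        c = _numeric_cohort({"x": np.arange(10.0)})
        with pytest.raises(ValueError):
            umap_coverage(c, c.copy(), n_neighbors=50)


class TestCompareDescriptives:
    def test_identical_columns_p_one(self, epad_clean):
        out = compare_descriptives(epad_clean, epad_clean.copy())
        for key, p in out.items():
            if not math.isnan(p):
                assert p == pytest.approx(1.0)

    def test_large_mean_difference_rejected(self):
        rng = np.random.default_rng(9)
        r = _numeric_cohort({"x": rng.standard_normal(1000)})
        s = _numeric_cohort({"x": rng.standard_normal(1000) + 1.0})
        assert compare_descriptives(r, s)["x"] < 1e-6

    def test_degenerate_variance_undefined(self):
        r = _numeric_cohort({"x": np.zeros(10)})
        s = _numeric_cohort({"x": np.ones(10)})
        assert math.isnan(compare_descriptives(r, s)["x"])

    def test_equal_proportions_p_one(self):
        schema = CohortSchema([VariableSpec("g", "categorical", levels=("a", "b"))])
        r = Cohort(schema, pd.DataFrame({"g": ["a", "b"] * 10}))
        s = Cohort(schema, pd.DataFrame({"g": ["a", "b"] * 25}))
        out = compare_descriptives(r, s)
        assert out["g=a"] == pytest.approx(1.0)
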