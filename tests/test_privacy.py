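import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from synthqc.cohort_table import Cohort, CohortSchema, VariableSpec
from synthqc.privacy import MISSING_CODE, bin_cohorts, dcr_report, record_distance


def _numeric_cohort(columns: dict, label="real") -> Cohort:
    schema = CohortSchema([VariableSpec(n, "numeric") for n in columns])
    return Cohort(schema, pd.DataFrame({k: pd.Series(v, dtype=float)
                                        for k, v in columns.items()}), label)


class TestBinning:
    def test_equal_width_arithmetic(self):
        vals = np.arange(0.0, 101.0)
        real = _numeric_cohort({"x": vals})
        syn = _numeric_cohort({"x": vals}, label="synthetic")
        br, _ = bin_cohorts(real, syn, n_bins=25)
        # range 0..100, 25 bins of width 4: value 7 -> bin 1 (0-based)
        assert br.codes[7, 0] == 1
        assert br.codes[0, 0] == 0

    def test_maximum_lands_in_last_bin(self):
        real = _numeric_cohort({"x": np.arange(0.0, 101.0)})
        syn = _numeric_cohort({"x": np.arange(0.0, 101.0)}, label="synthetic")
        br, _ = bin_cohorts(real, syn, n_bins=25)
        assert br.codes[100, 0] == 24

    def test_shared_edges_between_cohorts(self):
        real = _numeric_cohort({"x": np.array([0.0, 10.0])})
        syn = _numeric_cohort({"x": np.array([20.0, 30.0])})
        br, bs = bin_cohorts(real, syn, n_bins=3)
        # pooled range 0..30, width 10
        assert list(br.codes[:, 0]) == [0, 1]
        assert list(bs.codes[:, 0]) == [2, 2]

    def test_categorical_passthrough(self):
        schema = CohortSchema([VariableSpec("g", "categorical", levels=("a", "b")),
                               VariableSpec("x", "numeric")])
        real = Cohort(schema, pd.DataFrame({"g": ["a", "b", None],
                                            "x": [1.0, 2.0, 3.0]}))
        br, _ = bin_cohorts(real, real.copy(), n_bins=25)
        assert list(br.codes[:, 0]) == [0, 1, MISSING_CODE]

    def test_zero_range_single_bin(self):
        real = _numeric_cohort({"x": np.full(5, 3.0)})
        br, _ = bin_cohorts(real, real.copy(), n_bins=25)
        assert set(br.codes[:, 0]) == {0}

    def test_missing_gets_dedicated_category(self):
        real = _numeric_cohort({"x": np.array([1.0, np.nan, 3.0])})
        br, _ = bin_cohorts(real, real.copy(), n_bins=4)
        assert br.codes[1, 0] == MISSING_CODE


class TestRecordDistance:
    def test_identity_zero(self):
        x = np.array([1, 2, 3])
        assert record_distance(x, x) == 0

    def test_positionwise_count(self):
        # same bin, differing sex and genotype -> distance 2
        x = np.array([12, 0, 2])
        y = np.array([12, 1, 3])
        assert record_distance(x, y) == 2

    def test_maximum_distance(self):
        p = 11
        x = np.zeros(p, dtype=int)
        y = np.ones(p, dtype=int)
        assert record_distance(x, y) == p

    def test_missing_matches_missing_by_default(self):
        x = np.array([MISSING_CODE, 1])
        y = np.array([MISSING_CODE, 2])
        assert record_distance(x, y) == 1
        assert record_distance(x, y, missing_matches=False) == 2

    @given(st.integers(2, 10), st.integers(0, 1000))
    def test_metric_properties(self, p, seed):
        rng = np.random.default_rng(seed)
        x, y, z = (rng.integers(-1, 3, size=p) for _ in range(3))
        dxy = record_distance(x, y)
        assert dxy >= 0
        assert dxy == record_distance(y, x)
        assert dxy <= record_distance(x, z) + record_distance(z, y)

    def test_removing_variable_never_increases_distance(self):
        rng = np.random.default_rng(31)
        x = rng.integers(0, 5, size=8)
        y = rng.integers(0, 5, size=8)
        full = record_distance(x, y)
        for j in range(8):
            reduced = record_distance(np.delete(x, j), np.delete(y, j))
            assert reduced <= full


class TestDcrReport:
    def test_memorized_copy_flags_zero_ratio(self):
        rng = np.random.default_rng(32)
        real = _numeric_cohort({"x": rng.standard_normal(100),
                                "y": rng.standard_normal(100)})
        rep = dcr_report(real, real.copy(label="synthetic"))
        assert (rep.dcr_syn_to_real == 0).all()
        assert rep.mean_dcr_ratio == 0.0

    def test_duplicated_real_records_ratio_undefined(self):
        real = _numeric_cohort({"x": np.array([1.0, 1.0, 1.0]),
                                "y": np.array([2.0, 2.0, 2.0])})
        syn = _numeric_cohort({"x": np.array([5.0]), "y": np.array([5.0])})
        with pytest.warns(UserWarning, match="undefined"):
            rep = dcr_report(real, syn)
        assert np.isnan(rep.mean_dcr_ratio)
        assert rep.warning

    def test_independent_copula_sample_ratio_near_one(self, epad_clean):
        from synthqc.synthesizer import fit_synthesizer, sample_synthetic

        m = fit_synthesizer(epad_clean, seed=0)
        syn = sample_synthetic(m, epad_clean.n_records, seed=1)
        rep = dcr_report(epad_clean, syn)
        assert 0.8 <= rep.mean_dcr_ratio <= 1.2

    def test_bruteforce_oracle_small_instance(self):
        rng = np.random.default_rng(33)
        real = _numeric_cohort({"a": rng.standard_normal(120),
                                "b": rng.standard_normal(120),
                                "c": rng.standard_normal(120)})
        syn = _numeric_cohort({"a": rng.standard_normal(80),
                               "b": rng.standard_normal(80),
                               "c": rng.standard_normal(80)}, label="synthetic")
        rep = dcr_report(real, syn, n_bins=5)
        br, bs = bin_cohorts(real, syn, n_bins=5)
        # double-loop oracle
        for i in range(bs.n_records):
            expected = min(record_distance(bs.codes[i], br.codes[j])
                           for j in range(br.n_records))
            assert rep.dcr_syn_to_real[i] == expected
        for i in range(br.n_records):
            expected = min(record_distance(br.codes[i], br.codes[j])
                           for j in range(br.n_records) if j != i)
            assert rep.dcr_real_to_real[i] == expected

    def test_histogram_counts_sum_to_n(self, epad_clean):
        rep = dcr_report(epad_clean, epad_clean.copy(label="synthetic"))
        assert sum(rep.histogram("syn").values()) == epad_clean.n_records
        assert sum(rep.histogram("real").values()) == epad_clean.n_records

    def test_single_record_known_distance(self):
        real = _numeric_cohort({"a": np.array([0.0, 50.0]),
                                "b": np.array([0.0, 50.0]),
                                "c": np.array([0.0, 50.0]),
                                "d": np.array([0.0, 50.0])})
        # one synthetic record: same d-bin as record 0, different a, b, c bins
        syn = _numeric_cohort({"a": np.array([50.0]), "b": np.array([50.0]),
                               "c": np.array([50.0]), "d": np.array([0.0])},
                              label="synthetic")
        rep = dcr_report(real, syn, n_bins=2)
        assert rep.dcr_syn_to_real[0] == 1  # closest is record 1 (d differs)
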