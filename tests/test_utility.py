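import math

import numpy as np
import pandas as pd
import pytest

from synthqc.cohort_table import Cohort, CohortSchema, VariableSpec
from synthqc.utility import ndcg, outcome_auc, shap_importances, utility_comparison


def _cohort_with_outcome(columns: dict, y: np.ndarray, label="real") -> Cohort:
    specs = [VariableSpec(n, "numeric") for n in columns]
    specs.append(VariableSpec("y", "categorical", levels=("neg", "pos")))
    schema = CohortSchema(specs)
    data = {k: pd.Series(v, dtype=float) for k, v in columns.items()}
    data["y"] = pd.Series(np.where(y == 1, "pos", "neg"), dtype=object)
    return Cohort(schema, pd.DataFrame(data, columns=schema.names), label)


@pytest.fixture(scope="module")
def logistic_fixture():
    """Binary outcome from a known logistic model on two covariates."""
    rng = np.random.default_rng(21)
    n = 3000
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    eta = 0.8 * x1 + 0.4 * x2
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
    return _cohort_with_outcome({"x1": x1, "x2": x2}, y), eta


class TestOutcomeAuc:
    def test_no_signal_near_half(self):
        rng = np.random.default_rng(22)
        y = (rng.uniform(size=2000) < 0.3).astype(int)
        c = _cohort_with_outcome({"x1": rng.standard_normal(2000),
                                  "x2": rng.standard_normal(2000)}, y)
        mean, _ = outcome_auc(c, "y", ["x1", "x2"], n_repeats=3, seed=1)
        assert mean == pytest.approx(0.5, abs=0.05)

    def test_single_feature_signal_near_perfect(self):
        rng = np.random.default_rng(23)
        x = rng.standard_normal(1000)
        y = (x > 0).astype(int)
        c = _cohort_with_outcome({"x": x, "noise": rng.standard_normal(1000)}, y)
        mean, _ = outcome_auc(c, "y", ["x", "noise"], n_repeats=3, seed=2)
        assert mean > 0.95

    def test_logistic_recovers_population_auc(self, logistic_fixture):
        """CV AUC of the logistic model matches the generating model's AUC."""
        from sklearn.metrics import roc_auc_score

        cohort, eta = logistic_fixture
        y = (cohort.data["y"] == "pos").astype(int)
        pop_auc = roc_auc_score(y, eta)  # oracle: true linear predictor
        mean, _ = outcome_auc(cohort, "y", ["x1", "x2"],
                              model_kind="logistic", n_repeats=5, seed=3)
        assert mean == pytest.approx(pop_auc, abs=0.05)

    def test_single_class_outcome_raises(self):
        rng = np.random.default_rng(24)
        c = _cohort_with_outcome({"x": rng.standard_normal(50)}, np.zeros(50))
        with pytest.raises(ValueError, match="single class"):
            outcome_auc(c, "y", ["x"])

    def test_empty_predictors_raise(self, logistic_fixture):
        with pytest.raises(ValueError, match="empty"):
            outcome_auc(logistic_fixture[0], "y", [])

    def test_shuffle_invariance_of_mean(self, logistic_fixture):
        cohort, _ = logistic_fixture
        rng = np.random.default_rng(25)
        perm = rng.permutation(cohort.n_records)
        shuffled = Cohort(cohort.schema,
                          cohort.data.iloc[perm].reset_index(drop=True))
        a, sa = outcome_auc(cohort, "y", ["x1", "x2"], n_repeats=3, seed=4)
        b, sb = outcome_auc(shuffled, "y", ["x1", "x2"], n_repeats=3, seed=4)
        assert a == pytest.approx(b, abs=3 * (sa + sb + 1e-3))


class TestShapImportances:
    def test_single_signal_dominates(self):
        rng = np.random.default_rng(26)
        x = rng.standard_normal(1500)
        y = (x + 0.3 * rng.standard_normal(1500) > 0).astype(int)
        c = _cohort_with_outcome({
            "signal": x,
            "n1": rng.standard_normal(1500),
            "n2": rng.standard_normal(1500),
        }, y)
        imp = shap_importances(c, "y", ["signal", "n1", "n2"], seed=5)
        assert imp[0][0] == "signal"
        assert imp[0][1] >= 5 * max(v for f, v in imp if f != "signal")

    def test_two_signal_ordering_stable_across_seeds(self):
        rng = np.random.default_rng(27)
        n = 2000
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        eta = 2.0 * a + 1.0 * b
        y = (eta + rng.standard_normal(n) > 0).astype(int)
        c = _cohort_with_outcome({"a": a, "b": b}, y)
        wins = sum(
            shap_importances(c, "y", ["a", "b"], seed=s)[0][0] == "a"
            for s in range(20)
        )
        assert wins >= 18


class TestNdcg:
    def test_identity(self):
        ref = [("a", 3.0), ("b", 2.0), ("c", 1.0)]
        assert ndcg(ref, ["a", "b", "c"]) == 1.0

    def test_top_two_swap(self):
        ref = [("a", 3.0), ("b", 2.0), ("c", 1.0)]
        assert ndcg(ref, ["b", "a", "c"]) == pytest.approx(4.39279 / 4.76186,
                                                           abs=1e-4)

    def test_equal_relevances_any_order(self):
        ref = [("a", 2.0), ("b", 2.0), ("c", 2.0)]
        assert ndcg(ref, ["c", "a", "b"]) == pytest.approx(1.0)

    def test_scale_invariance(self):
        ref = [("a", 3.0), ("b", 2.0), ("c", 1.0)]
        scaled = [(f, 10 * v) for f, v in ref]
        assert ndcg(ref, ["c", "b", "a"]) == pytest.approx(
            ndcg(scaled, ["c", "b", "a"]))

    def test_feature_set_mismatch_raises(self):
        with pytest.raises(ValueError, match="feature set"):
            ndcg([("a", 1.0)], ["b"])

    def test_bruteforce_oracle_random_instances(self):
        """Direct DCG summation oracle on random relevance vectors."""
        rng = np.random.default_rng(28)
        for _ in range(30):
            p = rng.integers(2, 8)
            rel = rng.uniform(0.1, 5.0, size=p)
            names = [f"f{i}" for i in range(p)]
            order = np.argsort(-rel)
            ref = [(names[i], float(rel[i])) for i in order]
            cand = list(rng.permutation(names))
            dcg_c = sum(rel[names.index(f)] / math.log2(i + 2)
                        for i, f in enumerate(cand))
            dcg_r = sum(rel[i] / math.log2(k + 2)
                        for k, i in enumerate(order))
            assert ndcg(ref, cand) == pytest.approx(dcg_c / dcg_r, abs=1e-12)


class TestUtilityComparison:
    def test_self_copy_close_aucs_and_high_ndcg(self, epad_clean):
        rep = utility_comparison(epad_clean, epad_clean.copy(label="synthetic"),
                                 "abeta_lt_1000", n_repeats=3, seed=6)
        for model in ("gbt", "logistic"):
            (mr, sr), (ms, ss) = rep.auc[("real", model)], rep.auc[("syn", model)]
            assert abs(mr - ms) < 2 * (sr + ss) + 0.02
        assert rep.ndcg >= 0.9

    def test_report_structure_complete(self, epad_clean):
        from synthqc.synthesizer import fit_synthesizer, sample_synthetic

        m = fit_synthesizer(epad_clean, seed=0)
        syn = sample_synthetic(m, epad_clean.n_records, seed=1)
        rep = utility_comparison(epad_clean, syn, "abeta_lt_1000",
                                 n_repeats=2, seed=7)
        assert set(rep.auc) == {("real", "gbt"), ("real", "logistic"),
                                ("syn", "gbt"), ("syn", "logistic")}
        assert 0 < rep.ndcg <= 1

    def test_destroyed_signal_drops_syn_auc(self):
        rng = np.random.default_rng(29)
        n = 2000
        x = rng.standard_normal(n)
        y = (x + 0.5 * rng.standard_normal(n) > 0).astype(int)
        real = _cohort_with_outcome({"x": x, "n1": rng.standard_normal(n)}, y)
        # synthetic with the predictor-outcome link destroyed by permutation
        syn_df = real.data.copy()
        syn_df["x"] = syn_df["x"].to_numpy()[rng.permutation(n)]
        syn = Cohort(real.schema, syn_df, label="synthetic")
        auc_real, _ = outcome_auc(real, "y", ["x", "n1"], n_repeats=3, seed=8)
        auc_syn, _ = outcome_auc(syn, "y", ["x", "n1"], n_repeats=3, seed=8)
        assert auc_real > 0.85
        assert auc_syn == pytest.approx(0.5, abs=0.06)
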