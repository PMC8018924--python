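import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from solvtherm.evaluation import (
    MetricSet,
    PredictionTable,
    consensus,
    exclude,
    grouped_metrics,
    metrics,
)
from solvtherm.fixtures import (
    SAMPL5_OUTLIERS,
    sampl2_prediction_table,
    sampl5_prediction_table,
)


def table(y_exp, y_calc, **kw):
    ids = tuple(f"id{i}" for i in range(len(y_exp)))
    return PredictionTable(ids=ids, y_exp=np.asarray(y_exp), y_calc=np.asarray(y_calc), **kw)


class TestMetrics:
    def test_perfect_prediction(self):
        m = metrics(table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert (m.rmse, m.mae, m.mse) == (0.0, 0.0, 0.0)
        assert m.m_prime == pytest.approx(1.0)
        assert m.b_prime == pytest.approx(0.0, abs=1e-12)
        assert m.r2 == pytest.approx(1.0)

    def test_exact_affine_prediction(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = 2.0 * x + 1.0
        m = metrics(table(x, y))
        assert m.m_prime == pytest.approx(2.0)
        assert m.b_prime == pytest.approx(1.0)
        assert m.r2 == pytest.approx(1.0)
        e = y - x
        assert m.rmse == pytest.approx(np.sqrt(np.mean(e**2)))
        assert m.mse == pytest.approx(np.mean(e))

    def test_tautomer_test_set_statistics(self):
        # blind-test reactions of the partition-function water model: the
        # printed summary values recompute from the two-decimal inputs
        g = grouped_metrics(sampl2_prediction_table("SAMPL6/Z"))["obscure"]
        assert g.n == 8
        assert g.rmse == pytest.approx(1.59, abs=0.01)
        assert g.mse == pytest.approx(1.26, abs=0.02)  # input rounding at 2 decimals

    def test_population_variance_identity(self, rng):
        t = table(rng.normal(size=40), rng.normal(size=40))
        m = metrics(t)
        e = t.y_calc - t.y_exp
        assert m.rmse**2 == pytest.approx(m.mse**2 + np.var(e), abs=1e-10)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False), st.floats(-50, 50, allow_nan=False)
            ),
            min_size=2,
            max_size=30,
        )
    )
    def test_metric_ordering_invariant(self, pairs):
        x, y = zip(*pairs)
        m = metrics(table(list(x), list(y)))
        assert m.rmse >= m.mae - 1e-12
        assert m.mae >= abs(m.mse) - 1e-12
        if m.r2 is not None:
            assert -1e-12 <= m.r2 <= 1 + 1e-12

    def test_permutation_invariance(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        m1 = metrics(table(x, y))
        perm = rng.permutation(15)
        m2 = metrics(table(x[perm], y[perm]))
        assert m1.rmse == pytest.approx(m2.rmse, abs=1e-12)
        assert m1.m_prime == pytest.approx(m2.m_prime, abs=1e-10)

    def test_zero_experimental_variance_marks_regression_undefined(self):
        m = metrics(table([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))
        assert m.m_prime is None and m.b_prime is None and m.r2 is None
        assert np.isfinite(m.rmse)

    def test_missing_flagged_rows_excluded_not_dropped(self):
        t = PredictionTable(
            ids=("a", "b", "c"),
            y_exp=np.array([1.0, 2.0, 3.0]),
            y_calc=np.array([1.0, np.nan, 3.0]),
            missing=frozenset({"b"}),
        )
        assert len(t) == 3
        assert metrics(t).n == 2

    def test_unflagged_nan_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            table([1.0, 2.0], [1.0, np.nan])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PredictionTable(
                ids=("a", "a"), y_exp=np.zeros(2), y_calc=np.zeros(2)
            )


class TestExclude:
    def test_identity(self):
        t = sampl5_prediction_table()
        assert len(exclude(t, [])) == len(t)

    def test_count_and_provenance(self):
        t = table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = exclude(t, ["id1"])
        assert len(out) == 2
        assert any("id1" in p for p in out.provenance)

    def test_unknown_id_warns(self):
        t = table([1.0, 2.0], [1.0, 2.0])
        with pytest.warns(UserWarning, match="unknown"):
            exclude(t, ["nope"])

    def test_cannot_exclude_everything(self):
        t = table([1.0], [1.0])
        with pytest.raises(ValueError):
            exclude(t, ["id0"])

    def test_published_outlier_exclusion(self):
        t = sampl5_prediction_table(model="2-par-I", observable="logD")
        reduced = metrics(exclude(t, SAMPL5_OUTLIERS))
        assert reduced.n == 45
        assert reduced.rmse == pytest.approx(1.37, abs=0.01)


class TestConsensus:
    def test_identical_methods(self):
        t = table([1.0, 2.0], [1.5, 2.5])
        cons, cross = consensus(t, t)
        np.testing.assert_allclose(cons.y_calc, t.y_calc)
        assert cross.rmse == 0.0

    def test_symmetric_errors_cancel(self):
        truth = np.array([0.0, 1.0, -2.0, 3.0])
        delta = np.array([0.5, -1.0, 2.0, 0.1])
        a = table(truth, truth + delta)
        b = table(truth, truth - delta)
        cons, _ = consensus(a, b)
        assert metrics(cons).rmse == pytest.approx(0.0, abs=1e-12)

    def test_known_offsets_and_symmetry(self, rng):
        truth = rng.normal(size=10)
        a = table(truth, truth + 1.0)
        b = table(truth, truth - 0.5)
        cons, cross_ab = consensus(a, b)
        np.testing.assert_allclose(cons.y_calc, truth + 0.25)
        assert cross_ab.rmse == pytest.approx(1.5)
        _, cross_ba = consensus(b, a)
        assert cross_ab.rmse == pytest.approx(cross_ba.rmse)

    def test_disjoint_ids_rejected(self):
        a = PredictionTable(ids=("x",), y_exp=np.zeros(1), y_calc=np.zeros(1))
        b = PredictionTable(ids=("y",), y_exp=np.zeros(1), y_calc=np.zeros(1))
        with pytest.raises(ValueError, match="common"):
            consensus(a, b)


class TestGroupedMetrics:
    def test_single_group_equals_pooled(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        t = table(x, y, group=("g",) * 8)
        out = grouped_metrics(t)
        assert out["g"].rmse == pytest.approx(out["all"].rmse)

    def test_tautomer_bias_by_subset(self):
        # original-submission partition-function column: training/test bias
        # and the pooled value over all 20 reactions
        out = grouped_metrics(sampl2_prediction_table("SAMPL2/Z"))
        assert out["obscure"].mse == pytest.approx(-2.53, abs=0.01)
        assert out["explanatory"].mse == pytest.approx(0.21, abs=0.01)
        assert out["all"].mse == pytest.approx(-0.94, abs=0.01)
        assert out["all"].n == 20  # includes the high-uncertainty diketo pairs

    def test_identical_groups_identical_metrics(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=5)
        t = PredictionTable(
            ids=tuple(f"i{k}" for k in range(10)),
            y_exp=np.concatenate([x, x]),
            y_calc=np.concatenate([y, y]),
            group=("a",) * 5 + ("b",) * 5,
        )
        out = grouped_metrics(t)
        assert out["a"].rmse == pytest.approx(out["b"].rmse)

    def test_pooled_mse_is_weighted_group_mean(self, rng):
        n1, n2 = 7, 13
        t = PredictionTable(
            ids=tuple(f"i{k}" for k in range(n1 + n2)),
            y_exp=rng.normal(size=n1 + n2),
            y_calc=rng.normal(size=n1 + n2),
            group=("a",) * n1 + ("b",) * n2,
        )
        out = grouped_metrics(t)
        pooled = (n1 * out["a"].mse + n2 * out["b"].mse) / (n1 + n2)
        assert out["all"].mse == pytest.approx(pooled, abs=1e-10)
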