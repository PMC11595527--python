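import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corridorscape import sdm
from corridorscape.raster import GridContract, Raster
from corridorscape.synthland import LandscapeSpec, Hotspot, make_suitability

from oracles import pairwise_auc, vif_by_regression


def occ_frame(presence_xy, background_xy=()):
    rows = [
        {"id": i, "x": x, "y": y, "label": "presence", "source": "field"}
        for i, (x, y) in enumerate(presence_xy)
    ]
    rows += [
        {"id": len(rows) + i, "x": x, "y": y, "label": "background", "source": "background"}
        for i, (x, y) in enumerate(background_xy)
    ]
    return pd.DataFrame(rows)


class TestThinning:
    def test_widely_spaced_points_all_retained(self):
        occ = occ_frame([(0, 0), (2000, 0), (0, 2000), (2000, 2000)])
        assert len(sdm.thin_occurrences(occ, 1000)) == 4

    def test_close_pair_keeps_first_in_order(self):
        occ = occ_frame([(0, 0), (500, 0)])
        thinned = sdm.thin_occurrences(occ, 1000)
        assert len(thinned) == 1
        assert thinned.iloc[0]["x"] == 0

    def test_collinear_chain_keeps_first_and_third(self):
        occ = occ_frame([(0, 0), (800, 0), (1600, 0)])
        thinned = sdm.thin_occurrences(occ, 1000)
        assert list(thinned["x"]) == [0, 1600]
        xy = thinned[["x", "y"]].to_numpy(dtype=float)
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).T)
        assert d[~np.eye(len(xy), dtype=bool)].min() >= 1000

    def test_background_points_untouched(self):
        occ = occ_frame([(0, 0), (100, 0)], background_xy=[(0, 0), (10, 0)])
        thinned = sdm.thin_occurrences(occ, 1000)
        assert (thinned["label"] == "background").sum() == 2

    def test_idempotent_on_random_clouds(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 5000, size=(60, 2))
        occ = occ_frame(pts)
        once = sdm.thin_occurrences(occ, 1000)
        twice = sdm.thin_occurrences(once, 1000)
        pd.testing.assert_frame_equal(once, twice)


def _stack_from_columns(grid, **cols):
    return {
        name: Raster(np.asarray(vals, dtype=float).reshape(grid.height, grid.width), grid)
        for name, vals in cols.items()
    }


class TestVifScreen:
    def _points_on_grid(self, grid, n):
        rng = np.random.default_rng(5)
        rows = rng.integers(0, grid.height, n)
        cols = rng.integers(0, grid.width, n)
        xs = grid.origin[0] + (cols + 0.5) * grid.cell_size
        ys = grid.origin[1] - (rows + 0.5) * grid.cell_size
        return occ_frame(list(zip(xs, ys)))

    def test_orthogonal_layers_both_retained(self):
        grid = GridContract(4, 4, 300.0)
        # two exactly orthogonal patterns over the 16 cells
        a = np.tile([1.0, -1.0], 8)
        b = np.repeat([1.0, -1.0], 8)
        stack = _stack_from_columns(grid, a=a, b=b)
        pts = self._points_on_grid(grid, 0)
        rows, cols = np.meshgrid(range(4), range(4), indexing="ij")
        xs = (cols.ravel() + 0.5) * 300.0
        ys = -(rows.ravel() + 0.5) * 300.0
        pts = occ_frame(list(zip(xs, ys)))
        retained, trace = sdm.vif_screen(stack, pts)
        assert retained == ["a", "b"]
        assert np.allclose(trace["vif"], 1.0)

    def test_duplicated_layer_removed(self):
        rng = np.random.default_rng(1)
        grid = GridContract(6, 6, 300.0)
        base = rng.normal(size=36)
        stack = _stack_from_columns(grid, a=base, b=base.copy(), c=rng.normal(size=36))
        rows, cols = np.meshgrid(range(6), range(6), indexing="ij")
        pts = occ_frame(list(zip((cols.ravel() + 0.5) * 300.0, -(rows.ravel() + 0.5) * 300.0)))
        retained, _ = sdm.vif_screen(stack, pts)
        assert len([n for n in retained if n in ("a", "b")]) == 1
        assert "c" in retained

    def test_near_collinear_layer_removed_and_survivors_match_oracle(self):
        rng = np.random.default_rng(2)
        grid = GridContract(10, 10, 300.0)
        x1 = rng.normal(size=100)
        x2 = rng.normal(size=100)
        x3 = x1 + x2 + rng.normal(0, 0.01, size=100)
        stack = _stack_from_columns(grid, x1=x1, x2=x2, x3=x3)
        rows, cols = np.meshgrid(range(10), range(10), indexing="ij")
        pts = occ_frame(list(zip((cols.ravel() + 0.5) * 300.0, -(rows.ravel() + 0.5) * 300.0)))
        retained, _ = sdm.vif_screen(stack, pts)
        assert len(retained) == 2
        X = np.column_stack([stack[n].data.ravel() for n in retained])
        assert np.all(vif_by_regression(X) < 10)

    def test_constant_layer_removed_with_warning(self):
        rng = np.random.default_rng(3)
        grid = GridContract(5, 5, 300.0)
        stack = _stack_from_columns(grid, flat=np.ones(25), a=rng.normal(size=25))
        rows, cols = np.meshgrid(range(5), range(5), indexing="ij")
        pts = occ_frame(list(zip((cols.ravel() + 0.5) * 300.0, -(rows.ravel() + 0.5) * 300.0)))
        with pytest.warns(UserWarning, match="constant"):
            retained, _ = sdm.vif_screen(stack, pts)
        assert retained == ["a"]


class TestSplit:
    def _occ(self, n_pres, n_back):
        return occ_frame(
            [(i * 2000.0, 0.0) for i in range(n_pres)],
            [(i * 2000.0, 5000.0) for i in range(n_back)],
        )

    def test_modeling_set_split_counts(self):
        # 196 presences at 75/25 -> 147 train / 49 test
        train, test = sdm.split_train_test(self._occ(196, 196), 0.75, seed=0)
        assert (train["label"] == "presence").sum() == 147
        assert (test["label"] == "presence").sum() == 49

    def test_minimal_split_floors_test_size(self):
        train, test = sdm.split_train_test(self._occ(4, 0), 0.75, seed=0)
        assert (train["label"] == "presence").sum() == 3
        assert (test["label"] == "presence").sum() == 1

    def test_split_is_disjoint_exhaustive_and_deterministic(self):
        occ = self._occ(20, 15)
        t1, s1 = sdm.split_train_test(occ, 0.75, seed=9)
        t2, s2 = sdm.split_train_test(occ, 0.75, seed=9)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(s1, s2)
        assert set(t1["id"]) | set(s1["id"]) == set(occ["id"])
        assert not (set(t1["id"]) & set(s1["id"]))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            sdm.split_train_test(self._occ(10, 10), 1.5, seed=0)


class TestScores:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([True, True, False, False])
        assert sdm.auc_score(scores, labels) == 1.0
        assert sdm.tss_score(scores, labels)[0] == 1.0

    def test_all_tied_scores_give_half(self):
        assert sdm.auc_score(np.full(6, 0.4), np.array([1, 1, 1, 0, 0, 0], bool)) == 0.5

    def test_worked_example(self):
        scores = np.array([0.9, 0.4, 0.8, 0.3])
        labels = np.array([True, True, False, False])
        assert sdm.auc_score(scores, labels) == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            sdm.auc_score(np.array([0.1, 0.2]), np.array([True, True]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_rank_auc_equals_pairwise_enumeration(self, data):
        n = data.draw(st.integers(2, 40))
        scores = np.array(data.draw(st.lists(st.integers(0, 10), min_size=n, max_size=n))) / 10.0
        n_pos = data.draw(st.integers(1, n - 1))
        labels = np.zeros(n, bool)
        labels[:n_pos] = True
        assert sdm.auc_score(scores, labels) == pytest.approx(
            pairwise_auc(scores, labels), abs=1e-12
        )


class TestGateAndWeight:
    def test_random_auc_gets_zero_raw_weight(self):
        res = sdm.gate_and_weight(
            [("m", sdm.EvalScores(auc=0.5, tss=0.8))], auc_min=0.0, tss_min=0.0
        )
        assert res.retained[0][1] == 0.0

    def test_raw_weight_formula(self):
        res = sdm.gate_and_weight([("m", sdm.EvalScores(auc=0.91, tss=0.86))])
        assert res.retained[0][1] == pytest.approx(0.1681)

    def test_two_learner_normalization(self):
        res = sdm.gate_and_weight(
            [("a", sdm.EvalScores(0.9, 0.8)), ("b", sdm.EvalScores(0.8, 0.75))]
        )
        raw = {lid: rw for lid, rw, _ in res.retained}
        norm = {lid: w for lid, _, w in res.retained}
        assert raw["a"] == pytest.approx(0.16) and raw["b"] == pytest.approx(0.09)
        assert norm["a"] == pytest.approx(0.64) and norm["b"] == pytest.approx(0.36)
        assert sum(norm.values()) == pytest.approx(1.0)

    def test_either_gate_failure_excludes(self):
        res = sdm.gate_and_weight(
            [
                ("good", sdm.EvalScores(0.85, 0.75)),
                ("low_tss", sdm.EvalScores(0.9, 0.6)),
                ("low_auc", sdm.EvalScores(0.7, 0.8)),
            ]
        )
        assert [lid for lid, *_ in res.retained] == ["good"]
        assert {lid for lid, _ in res.excluded} == {"low_tss", "low_auc"}

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError, match="gate"):
            sdm.gate_and_weight([("bad", sdm.EvalScores(0.6, 0.2))])


class _ConstLearner:
    def __init__(self, learner_id, value):
        self.learner_id = learner_id
        self.value = value

    def fit(self, X, y):
        return self

    def predict_score(self, X):
        return np.full(len(X), self.value)


class TestEnsemblePredict:
    def _stack(self):
        grid = GridContract(3, 3, 300.0)
        return grid, {"v": Raster(np.linspace(0, 1, 9).reshape(3, 3), grid)}

    def test_single_learner_passthrough(self):
        grid, stack = self._stack()
        res = sdm.EnsembleResult(retained=[("a", 0.16, 1.0)], excluded=[], scores={})
        out = sdm.ensemble_predict({"a": _ConstLearner("a", 0.3)}, res, stack, ["v"])
        assert np.allclose(out.data, 0.3)

    def test_equal_weights_average_constants(self):
        grid, stack = self._stack()
        res = sdm.EnsembleResult(
            retained=[("a", 1, 0.5), ("b", 1, 0.5)], excluded=[], scores={}
        )
        fits = {"a": _ConstLearner("a", 0.2), "b": _ConstLearner("b", 0.8)}
        assert np.allclose(sdm.ensemble_predict(fits, res, stack, ["v"]).data, 0.5)

    def test_unequal_weights(self):
        grid, stack = self._stack()
        res = sdm.EnsembleResult(
            retained=[("a", 0.16, 0.64), ("b", 0.09, 0.36)], excluded=[], scores={}
        )
        fits = {"a": _ConstLearner("a", 1.0), "b": _ConstLearner("b", 0.0)}
        assert np.allclose(sdm.ensemble_predict(fits, res, stack, ["v"]).data, 0.64)


class TestJackknife:
    @staticmethod
    def _factory():
        from sklearn.linear_model import LogisticRegression

        from corridorscape.learners import SklearnLearner

        return SklearnLearner("logit", LogisticRegression(max_iter=500))

    def test_informative_variable_dominates(self):
        rng = np.random.default_rng(4)
        n = 400
        y = rng.random(n) < 0.5
        X = np.column_stack(
            [y + rng.normal(0, 0.3, n), rng.normal(size=n), rng.normal(size=n)]
        )
        table = sdm.jackknife_importance(
            self._factory, X[: n // 2], y[: n // 2], X[n // 2 :], y[n // 2 :],
            ["signal", "noise1", "noise2"],
        )
        assert table["contribution_pct"].sum() == pytest.approx(100.0)
        assert table.loc[table["contribution_pct"].idxmax(), "variable"] == "signal"

    def test_duplicated_variables_compensate(self):
        rng = np.random.default_rng(6)
        n = 400
        y = rng.random(n) < 0.5
        sig = y + rng.normal(0, 0.3, n)
        X = np.column_stack([sig, sig])
        with pytest.warns(UserWarning, match="uniform contributions"):
            table = sdm.jackknife_importance(
                self._factory, X[: n // 2], y[: n // 2], X[n // 2 :], y[n // 2 :], ["a", "b"]
            )
        assert np.all(table["score"] < 0.02)


class TestBinarize:
    def test_recovers_truth_map_exactly(self, raster_factory):
        truth = np.zeros((6, 6))
        truth[2:4, 2:4] = 1.0
        suit = raster_factory(truth)
        scores = np.array([1.0, 1.0, 0.0, 0.0])
        labels = np.array([True, True, False, False])
        binary, thr = sdm.binarize_habitat(suit, scores, labels)
        assert np.array_equal(binary.data, truth.astype(int))

    def test_degenerate_test_set_falls_back(self, raster_factory):
        suit = raster_factory(np.full((4, 4), 0.6))
        with pytest.warns(UserWarning, match="degenerate"):
            binary, thr = sdm.binarize_habitat(
                suit, np.full(4, 0.5), np.array([1, 1, 0, 0], bool)
            )
        assert thr == 0.5
        assert np.all(binary.data == 1)


class TestMerge:
    def test_merge_reassigns_unique_ids(self):
        a = occ_frame([(0, 0), (5000, 0)])
        b = occ_frame([(10000, 0)])
        merged = sdm.merge_occurrences(a, b)
        assert len(merged) == 3 and merged["id"].is_unique
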