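import numpy as np
import pandas as pd
import pytest

from ptyrlink import plsr
from ptyrlink.synthetic import make_planted_regression
from ptyrlink.types import PtyrlinkError


def _problem(n, p, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"x{j}" for j in range(p)])
    beta = rng.normal(size=p)
    y = pd.Series(X.to_numpy() @ beta + rng.normal(scale=0.1, size=n))
    return X, y


class TestFitPlsr:
    def test_single_informative_feature_exact_fit(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=8)})
        y = 3.0 * X["a"] + 2.0
        model = plsr.fit_plsr(X, y, n_components=1)
        assert model.r2 == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("n,p", [(6, 2), (7, 3), (9, 4)])
    def test_full_rank_matches_ols(self, n, p):
        """At full rank, PLSR predictions equal the normal-equations fit."""
        X, y = _problem(n, p, seed=n * 10 + p)
        model = plsr.fit_plsr(X, y, n_components=p, scale=False)
        Xc = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y.to_numpy())
        ols_pred = Xc @ beta
        np.testing.assert_allclose(model.fitted, ols_pred, atol=1e-8)

    def test_constant_response_degenerates_cleanly(self):
        X, _ = _problem(6, 3)
        y = pd.Series(np.full(6, 4.2))
        model = plsr.fit_plsr(X, y, n_components=2)
        assert model.n_components == 0
        assert model.r2 == 0.0
        np.testing.assert_array_equal(model.coef, 0.0)
        np.testing.assert_allclose(model.predict(X), 4.2)

    def test_score_orthogonality(self):
        for seed in range(5):
            X, y = _problem(9, 6, seed=seed)
            model = plsr.fit_plsr(X, y, n_components=4)
            T = model.scores
            G = T.T @ T
            off = G - np.diag(np.diag(G))
            norms = np.sqrt(np.diag(G))
            assert np.abs(off).max() < 1e-8 * np.outer(norms, norms).max()

    def test_too_many_components_rejected(self):
        X, y = _problem(5, 3)
        with pytest.raises(PtyrlinkError, match="n_components"):
            plsr.fit_plsr(X, y, n_components=5)

    def test_zero_variance_feature_named(self):
        X, y = _problem(6, 2)
        X["flatline"] = 1.0
        with pytest.raises(PtyrlinkError, match="flatline"):
            plsr.fit_plsr(X, y, n_components=1, scale=True)

    def test_matches_sklearn_reference(self):
        """Independent cross-check against scikit-learn's PLS fit."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = _problem(10, 5, seed=42)
        model = plsr.fit_plsr(X, y, n_components=3, scale=True)
        ref = PLSRegression(n_components=3, scale=True).fit(
            X.to_numpy(), y.to_numpy()
        )
        np.testing.assert_allclose(
            model.fitted, ref.predict(X.to_numpy()).ravel(), atol=1e-8
        )


class TestLoocv:
    def test_noise_free_linear_q2_is_one(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        y = 2.0 * X["a"] - X["b"] + 1.0
        res = plsr.loocv(X, y, max_components=2)
        assert res.q2 == pytest.approx(1.0, abs=1e-8)

    def test_equals_hand_rolled_fold_loop(self):
        """Q^2 must agree exactly with an independently coded LOOCV loop."""
        X, y = _problem(5, 3, seed=8)
        res = plsr.loocv(X, y, max_components=2, scale=True)
        yv = y.to_numpy()
        for a in (1, 2):
            press = 0.0
            for i in range(5):
                mask = np.ones(5, dtype=bool)
                mask[i] = False
                model = plsr.fit_plsr(X.iloc[mask], y.iloc[mask],
                                      n_components=a, scale=True)
                pred = model.predict(X.iloc[[i]])[0]
                press += (yv[i] - pred) ** 2
            tss = ((yv - yv.mean()) ** 2).sum()
            assert res.q2_by_components.loc[a] == pytest.approx(
                1.0 - press / tss, abs=1e-12
            )

    def test_cap_warns_and_caps(self):
        X, y = _problem(4, 5)
        with pytest.warns(UserWarning, match="capped"):
            res = plsr.loocv(X, y, max_components=4)
        assert res.q2_by_components.index.max() == 2

    def test_selection_prefers_fewer_components_on_ties(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(12, 1)), columns=["a"])
        y = X["a"] * 2.0
        res = plsr.loocv(X, y, max_components=1)
        assert res.selected_n_components == 1


class TestVip:
    def test_single_feature_vip_is_one(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"only": rng.normal(size=8)})
        y = X["only"] * 1.5
        model = plsr.fit_plsr(X, y, n_components=1)
        table = plsr.vip(model)
        assert table.loc["only", "vip"] == pytest.approx(1.0, abs=1e-12)

    def test_orthonormal_case_sqrt2_and_zero(self):
        X = pd.DataFrame(
            {
                "signal": [1.0, -1.0, 1.0, -1.0],
                "inert": [1.0, 1.0, -1.0, -1.0],
            }
        )
        y = pd.Series([1.0, -1.0, 1.0, -1.0])
        model = plsr.fit_plsr(X, y, n_components=1, scale=False)
        table = plsr.vip(model)
        assert table.loc["signal", "vip"] == pytest.approx(np.sqrt(2),
                                                           abs=1e-8)
        assert table.loc["inert", "vip"] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_mean_squared_vip_identity(self, seed):
        X, y = _problem(9, 7, seed=seed)
        model = plsr.fit_plsr(X, y, n_components=3)
        v = plsr.vip(model)["vip"].to_numpy()
        assert np.mean(v**2) == pytest.approx(1.0, abs=1e-8)

    def test_threshold_flag(self):
        X, y = _problem(9, 7, seed=9)
        model = plsr.fit_plsr(X, y, n_components=2)
        table = plsr.vip(model, threshold=1.0)
        assert table["selected"].equals(table["vip"] > 1.0)


class TestCumulativeVip:
    def _models(self):
        X, y1 = _problem(9, 4, seed=11)
        _, y2 = _problem(9, 4, seed=12)
        return {
            "proliferation": plsr.fit_plsr(X, y1, n_components=2),
            "migration": plsr.fit_plsr(X, y2, n_components=2),
        }

    def test_single_model_equals_per_model_vip(self):
        models = self._models()
        single = {"proliferation": models["proliferation"]}
        table = plsr.cumulative_vip(single)
        per = plsr.vip(models["proliferation"])["vip"]
        np.testing.assert_allclose(table["cumulative_vip"].sort_index(),
                                   per.sort_index(), atol=1e-12)

    def test_sum_and_rank_order(self):
        models = self._models()
        table = plsr.cumulative_vip(models)
        manual = (plsr.vip(models["proliferation"])["vip"]
                  + plsr.vip(models["migration"])["vip"])
        np.testing.assert_allclose(table["cumulative_vip"].sort_index(),
                                   manual.sort_index(), atol=1e-12)
        ordered = table.sort_values("rank")["cumulative_vip"].to_numpy()
        assert (np.diff(ordered) <= 1e-12).all()

    def test_tied_scores_rank_lexicographically(self):
        X = pd.DataFrame(
            np.random.default_rng(1).normal(size=(8, 2)),
            columns=["zeta", "alpha"],
        )
        y = pd.Series(X.to_numpy().sum(axis=1))
        model = plsr.fit_plsr(X, y, n_components=1)
        table = plsr.cumulative_vip({"only": model})
        tied = table[np.isclose(table["cumulative_vip"],
                                table["cumulative_vip"].iloc[0])]
        if len(tied) > 1:
            assert list(tied.index) == sorted(tied.index)

    def test_feature_space_mismatch_rejected(self):
        models = self._models()
        Xb, yb = _problem(9, 3, seed=13)
        models["internalization"] = plsr.fit_plsr(Xb, yb, n_components=1)
        with pytest.raises(PtyrlinkError, match="feature space"):
            plsr.cumulative_vip(models)


class TestRobustness:
    def test_drop_nothing_is_identity(self):
        X, y = _problem(9, 4, seed=20)
        X.index = [f"L{i}" for i in range(9)]
        y.index = X.index
        res = plsr.robustness_refit(X, y, [])
        assert res.full == res.reduced
        assert res.vip_spearman == pytest.approx(1.0)

    def test_duplicate_line_removal_keeps_predictions(self):
        # exactly linear response: the fit is exact, so dropping a
        # duplicated observation cannot change predictions
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"),
                         index=[f"L{i}" for i in range(8)])
        X.loc["L7"] = X.loc["L0"]
        y = pd.Series(X.to_numpy() @ np.array([1.0, -2.0, 0.5]) + 3.0,
                      index=X.index)
        full = plsr.fit_plsr(X, y, n_components=3)
        keep = [i for i in X.index if i != "L7"]
        reduced = plsr.fit_plsr(X.loc[keep], y.loc[keep], n_components=3)
        np.testing.assert_allclose(
            full.predict(X.loc[keep]), reduced.predict(X.loc[keep]), atol=1e-8
        )

    def test_too_few_remaining_rejected(self):
        X, y = _problem(4, 3, seed=22)
        X.index = [f"L{i}" for i in range(4)]
        y.index = X.index
        with pytest.raises(PtyrlinkError, match="3 remaining"):
            plsr.robustness_refit(X, y, ["L0", "L1"])

    def test_planted_features_survive_line_removal(self):
        """Dropping 2 of 9 lines keeps planted features above the VIP
        selection threshold in >= 90% of seeds."""
        hits = 0
        for seed in range(20):
            X, y, planted = make_planted_regression(seed=seed)
            drop = list(X.index[:2])
            keep = [i for i in X.index if i not in drop]
            reduced = plsr.fit_plsr(X.loc[keep], y.loc[keep], n_components=3)
            table = plsr.vip(reduced, threshold=1.5)
            hits += bool(table.loc[planted, "selected"].all())
        assert hits >= 18


class TestQ2VersusR2:
    def test_q2_never_exceeds_r2_on_recovery_suite(self):
        for seed in range(8):
            X, y, _ = make_planted_regression(seed=seed)
            cv = plsr.loocv(X, y, max_components=3)
            model = plsr.fit_plsr(X, y, n_components=3)
            assert cv.q2 <= model.r2 + 1e-12
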