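import numpy as np
import pytest
from scipy.special import logsumexp

from rangeshift import maxent, synth
from rangeshift.bioclim import BIOCLIM_VARS
from rangeshift.errors import InvalidParameterError, TooFewRecordsError
from rangeshift.grids import GridSpec
from rangeshift.maxent import (
    MaxentSDM,
    SuitabilityMap,
    auc_score,
    build_background,
    entropy_equating_threshold,
    entropy_matching_count,
    fit_species,
    predict_logistic,
    screen,
)


def one_variable_problem():
    """3 background cells on one variable, presences favoring the top cell.

    The presence moments are attainable by an interior Gibbs distribution,
    so the optimum is finite and unique.
    """
    bg = np.array([[0.0], [0.5], [1.0]])
    pres = np.array([[1.0]] * 6 + [[0.5]] * 3 + [[0.0]] * 1)
    X = np.vstack([pres, bg])
    y = np.r_[np.ones(len(pres)), np.zeros(len(bg))]
    return X, y


class TestFit:
    def test_matches_grid_search_oracle_on_toy(self):
        """The optimizer agrees with nested-grid maximization of the exact
        penalized likelihood on a 1-variable toy (beta = 0)."""
        X, y = one_variable_problem()
        model = MaxentSDM(beta_multiplier=0.0, include_presences_in_background=False).fit(X, y)
        kept = model.feature_kept_
        F_bg = model.feature_space_.transform(X[y == 0])[:, kept]
        F_p = model.feature_space_.transform(X[y == 1])[:, kept]
        p_mean = F_p.mean(axis=0)

        def objective(lam):
            return p_mean @ lam - logsumexp(F_bg @ lam)

        # independent oracle: iterated grid refinement over lambda
        n = F_bg.shape[1]
        lo, hi = np.full(n, -50.0), np.full(n, 50.0)
        best = None
        for _round in range(8):
            axes = [np.linspace(lo[j], hi[j], 21) for j in range(n)]
            mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, n)
            vals = np.array([objective(lam) for lam in mesh])
            best = mesh[np.argmax(vals)]
            span = (hi - lo) / 10
            lo, hi = best - span, best + span
        lam_fit = model.lambda_[kept]
        assert objective(lam_fit) == pytest.approx(objective(best), abs=1e-6)
        np.testing.assert_allclose(lam_fit, best, atol=1e-2)

    def test_infinite_penalty_gives_uniform_model(self):
        X, y = one_variable_problem()
        model = MaxentSDM(beta_multiplier=1e9, include_presences_in_background=False).fit(X, y)
        assert np.allclose(model.lambda_, 0.0)
        assert model.entropy_ == pytest.approx(np.log(3))
        raw = model.raw(X[y == 0])
        np.testing.assert_allclose(raw, 1 / 3, atol=1e-12)

    def test_moment_matched_presences_keep_lambda_zero(self):
        """Presences distributed exactly like the background leave the
        uniform model stationary."""
        bg = np.array([[0.0], [0.25], [0.5], [0.75], [1.0]])
        X = np.vstack([bg, bg])
        y = np.r_[np.ones(5), np.zeros(5)]
        model = MaxentSDM(beta_multiplier=0.1, include_presences_in_background=False).fit(X, y)
        assert np.allclose(model.lambda_, 0.0, atol=1e-8)

    def test_too_few_presences_rejected(self):
        X = np.array([[0.0], [1.0], [0.5], [0.2], [0.8]])
        y = np.array([1, 1, 0, 0, 0])
        with pytest.raises(TooFewRecordsError):
            MaxentSDM().fit(X, y)

    def test_raw_distribution_sums_to_one(self, small_stack):
        """Conservation: the fitted Gibbs weights over background sum to 1."""
        rng = np.random.default_rng(0)
        Xbg = small_stack.to_matrix()
        pres = Xbg[rng.choice(len(Xbg), 30, replace=False)]
        X = np.vstack([pres, Xbg])
        y = np.r_[np.ones(len(pres)), np.zeros(len(Xbg))]
        model = MaxentSDM(include_presences_in_background=False).fit(X, y)
        assert model.raw(Xbg).sum() == pytest.approx(1.0, abs=1e-10)

    def test_kkt_conditions_hold_at_optimum(self, small_stack):
        rng = np.random.default_rng(1)
        Xbg = small_stack.to_matrix()
        weights = np.exp(-((Xbg[:, 0] - Xbg[:, 0].mean()) ** 2))
        pres = Xbg[rng.choice(len(Xbg), 40, p=weights / weights.sum())]
        X = np.vstack([pres, Xbg])
        y = np.r_[np.ones(len(pres)), np.zeros(len(Xbg))]
        model = MaxentSDM(beta_multiplier=0.05, include_presences_in_background=False).fit(X, y)
        kept = model.feature_kept_
        F_bg = model.feature_space_.transform(Xbg)[:, kept]
        F_p = model.feature_space_.transform(pres)[:, kept]
        lam = model.lambda_[kept]
        beta = model.beta_[kept]
        scores = F_bg @ lam
        w = np.exp(scores - logsumexp(scores))
        grad = F_p.mean(axis=0) - F_bg.T @ w  # d(loglik)/d(lambda)
        active = lam != 0
        assert (np.abs(grad[active]) <= beta[active] + 1e-5).all()

    def test_objective_is_globally_optimal_from_random_starts(self):
        """Convexity: random restarts of an independent optimizer never beat
        the returned objective (within 1e-6)."""
        from scipy.optimize import minimize

        X, y = one_variable_problem()
        model = MaxentSDM(beta_multiplier=0.1, include_presences_in_background=False).fit(X, y)
        kept = model.feature_kept_
        F_bg = model.feature_space_.transform(X[y == 0])[:, kept]
        F_p = model.feature_space_.transform(X[y == 1])[:, kept]
        p_mean = F_p.mean(axis=0)
        beta = model.beta_[kept]

        def neg_penalized(lam):
            return logsumexp(F_bg @ lam) - p_mean @ lam + beta @ np.abs(lam)

        fitted = neg_penalized(model.lambda_[kept])
        rng = np.random.default_rng(0)
        for _ in range(5):
            res = minimize(neg_penalized, rng.normal(0, 3, size=len(beta)),
                           method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            assert fitted <= res.fun + 1e-6


class TestPredict:
    def test_uniform_model_predicts_half_everywhere(self, small_stack):
        Xbg = small_stack.to_matrix()
        X = np.vstack([Xbg[:10], Xbg])
        y = np.r_[np.ones(10), np.zeros(len(Xbg))]
        model = MaxentSDM(beta_multiplier=1e9, include_presences_in_background=False).fit(X, y)
        smap = predict_logistic(model, small_stack)
        np.testing.assert_allclose(smap.values, 0.5, atol=1e-9)

    def test_logistic_is_monotone_in_raw(self, small_stack):
        rng = np.random.default_rng(3)
        Xbg = small_stack.to_matrix()
        pres = Xbg[rng.choice(len(Xbg), 25)]
        X = np.vstack([pres, Xbg])
        y = np.r_[np.ones(len(pres)), np.zeros(len(Xbg))]
        model = MaxentSDM().fit(X, y)
        raw = model.raw(Xbg)
        logi = model.predict_logistic(Xbg)
        order = np.argsort(raw)
        assert (np.diff(logi[order]) >= -1e-12).all()
        assert ((logi > 0) & (logi < 1)).all()

    def test_sklearn_estimator_contract(self):
        X, y = one_variable_problem()
        model = MaxentSDM(beta_multiplier=0.2)
        params = model.get_params()
        assert params["beta_multiplier"] == 0.2
        model.set_params(beta_multiplier=0.3).fit(X, y)
        proba = model.predict_proba(X)
        assert proba.shape == (len(X), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(model.predict(X)) <= {0, 1}
        assert 0.0 <= model.score(X, y) <= 1.0

    def test_json_roundtrip_preserves_predictions(self, small_stack, tmp_path):
        rng = np.random.default_rng(5)
        Xbg = small_stack.to_matrix()
        pres = Xbg[rng.choice(len(Xbg), 30)]
        X = np.vstack([pres, Xbg])
        y = np.r_[np.ones(len(pres)), np.zeros(len(Xbg))]
        model = MaxentSDM().fit(X, y)
        model.species_id_ = "spX"
        model.auc_ = model.score(X, y)
        path = tmp_path / "m.json"
        model.save_json(path)
        back = MaxentSDM.load_json(path)
        np.testing.assert_allclose(back.predict_logistic(Xbg), model.predict_logistic(Xbg))
        assert back.auc_ == model.auc_


class TestBackground:
    def test_all_cells_when_request_exceeds_landscape(self, small_stack):
        with pytest.warns(UserWarning, match="using all cells"):
            rows, cols = build_background(small_stack, 10_000, seed=0)
        assert len(rows) == small_stack.grid.n_cells

    def test_sample_is_deterministic(self, small_stack):
        a = build_background(small_stack, 50, seed=7)
        b = build_background(small_stack, 50, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        assert len(a[0]) == 50


class TestAuc:
    def test_perfect_separation(self):
        assert auc_score([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_all_ties_is_half(self):
        assert auc_score([0.5] * 10, [0.5] * 7) == 0.5

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(12)
        pres = np.round(rng.random(20), 2)  # rounding forces some ties
        bg = np.round(rng.random(30), 2)
        wins = sum(
            1.0 if p > b else (0.5 if p == b else 0.0) for p in pres for b in bg
        )
        assert auc_score(pres, bg) == pytest.approx(wins / (20 * 30), abs=1e-12)

    def test_empty_sets_rejected(self):
        with pytest.raises(InvalidParameterError):
            auc_score([], [0.5])


class TestScreen:
    class _Stub:
        def __init__(self, auc):
            self.auc_ = auc

    def test_boundary_and_exclusion(self):
        models = {"a": self._Stub(0.70), "b": self._Stub(0.69), "c": self._Stub(0.95)}
        kept, excluded = screen(models, 0.7)
        assert set(kept) == {"a", "c"}
        assert set(excluded) == {"b"}

    def test_empty_collection(self):
        assert screen({}, 0.7) == ({}, {})


class TestEntropyThreshold:
    def _uniform_model(self, stack):
        Xbg = stack.to_matrix()
        X = np.vstack([Xbg[:10], Xbg])
        y = np.r_[np.ones(10), np.zeros(len(Xbg))]
        return MaxentSDM(beta_multiplier=1e9, include_presences_in_background=False).fit(X, y)

    def test_uniform_distribution_keeps_every_cell(self, small_stack):
        model = self._uniform_model(small_stack)
        smap = predict_logistic(model, small_stack)
        thr = entropy_equating_threshold(model, smap)
        assert thr == pytest.approx(np.nanmin(smap.values))
        n_kept = np.sum(smap.values >= thr)
        assert n_kept == small_stack.grid.n_cells

    def test_point_mass_keeps_single_cell(self, small_stack):
        model = self._uniform_model(small_stack)
        model.entropy_ = 0.0  # degenerate raw distribution
        rng = np.random.default_rng(0)
        vals = rng.random(small_stack.grid.shape)
        smap = SuitabilityMap(values=vals, grid=small_stack.grid)
        thr = entropy_equating_threshold(model, smap)
        assert thr == vals.max()

    def test_count_matches_exhaustive_scan(self):
        rng = np.random.default_rng(17)
        for h in rng.uniform(0.0, np.log(100), size=25):
            k = entropy_matching_count(h, 100)
            best = min(range(1, 101), key=lambda kk: abs(np.log(kk) - h))
            assert k == best


def test_fit_species_deduplicates_and_requires_five_cells(small_stack):
    import pandas as pd

    g = small_stack.grid
    # 30 records but only 3 unique cells
    xs = [g.origin_x + 2.5] * 10 + [g.origin_x + 7.5] * 10 + [g.origin_x + 12.5] * 10
    ys = [g.origin_y + 2.5] * 30
    occ = pd.DataFrame({"x": xs, "y": ys})
    with pytest.warns(UserWarning, match="using all cells"):
        bg = build_background(small_stack, 10_000, seed=0)
    with pytest.raises(TooFewRecordsError):
        fit_species(occ, small_stack, bg, species_id="sp")
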