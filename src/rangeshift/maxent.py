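"""Maximum-entropy presence-background species distribution models.

The model is the Gibbs distribution over background cells that maximizes the
L1-penalized log-likelihood of the presence sample:

    l(lambda) = mean_presences lambda . f(x)  -  log Z(lambda)
                - sum_j beta_j |lambda_j|,
    Z(lambda) = sum_background exp(lambda . f(x)),

with features f built from the six bioclim covariates (linear, quadratic and
pairwise-product terms, min-max normalized on the background sample) and
per-feature penalties beta_j = beta_multiplier * sd_j(background) / sqrt(m).
The problem is concave with a unique optimal value; it is solved by L-BFGS-B
on the positive/negative split of lambda, and the returned optimum satisfies
the KKT conditions of the penalized problem.

``MaxentSDM`` follows the scikit-learn estimator contract (``fit(X, y)`` with
y = 1 for presence rows and 0 for background rows, ``predict_proba``,
``get_params``/``set_params``, trailing-underscore fitted attributes), so it
composes with sklearn pipelines and model selection.  The raster-facing
helpers (:func:`fit_species`, :func:`predict_logistic`,
:func:`entropy_equating_threshold`) wrap it for the projection pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .bioclim import BIOCLIM_VARS, ClimateStack
from .errors import (
    ConvergenceError,
    InvalidParameterError,
    SchemaError,
    TooFewRecordsError,
)
from .grids import GridSpec

__all__ = [
    "FeatureSpace",
    "MaxentSDM",
    "SuitabilityMap",
    "build_background",
    "fit_species",
    "predict_logistic",
    "auc_score",
    "screen",
    "entropy_equating_threshold",
    "entropy_matching_count",
]


@dataclass
class FeatureSpace:
    """Linear + quadratic + pairwise-product features with min-max normalizers.

    Normalizers are computed on the background sample so that normalized
    features lie in [0, 1] there; at prediction time features are clamped to
    the same [0, 1] training range.
    """

    variable_names: tuple[str, ...]
    feature_names: list[str] = field(default_factory=list)
    f_min: np.ndarray | None = None
    f_max: np.ndarray | None = None

    def _raw_features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != len(self.variable_names):
            raise SchemaError(
                f"expected (n, {len(self.variable_names)}) variable matrix, got {X.shape}"
            )
        cols = [X]
        cols.append(X**2)
        n_var = X.shape[1]
        prods = [X[:, i] * X[:, j] for i in range(n_var) for j in range(i + 1, n_var)]
        cols.append(np.column_stack(prods) if prods else np.empty((len(X), 0)))
        return np.hstack(cols)

    def fit(self, background: np.ndarray) -> "FeatureSpace":
        names = list(self.variable_names)
        names += [f"{v}^2" for v in self.variable_names]
        names += [
            f"{a}*{b}"
            for i, a in enumerate(self.variable_names)
            for b in self.variable_names[i + 1 :]
        ]
        self.feature_names = names
        F = self._raw_features(background)
        self.f_min = F.min(axis=0)
        self.f_max = F.max(axis=0)
        return self

    def transform(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        if self.f_min is None:
            raise SchemaError("FeatureSpace must be fit on background first")
        F = self._raw_features(X)
        span = self.f_max - self.f_min
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(span > 0, (F - self.f_min) / np.where(span > 0, span, 1.0), 0.0)
        if clamp:
            F = np.clip(F, 0.0, 1.0)
        return F


class MaxentSDM(BaseEstimator):
    """L1-regularized maximum-entropy presence-background classifier.

    Parameters
    ----------
    beta_multiplier : float
        Scales the per-feature L1 penalties; 0 disables regularization and
        large values drive all coefficients to zero (uniform suitability).
    include_presences_in_background : bool
        Add the presence rows to the background sum (the standard
        presence-background construction).
    max_iter : int
        Iteration cap for the optimizer.
    tol : float
        Target infinity-norm of the minimum-norm subgradient at the optimum.

    Attributes
    ----------
    feature_space_ : FeatureSpace fitted on the background sample.
    lambda_ : (n_features,) fitted coefficients.
    beta_ : (n_features,) per-feature penalty weights.
    log_z_ : log partition function over the background sample.
    entropy_ : entropy (nats) of the fitted raw distribution over background.
    n_background_ : number of background rows used in the partition sum.
    """

    def __init__(
        self,
        beta_multiplier: float = 0.001,
        include_presences_in_background: bool = True,
        max_iter: int = 1000,
        tol: float = 1e-6,
    ):
        self.beta_multiplier = beta_multiplier
        self.include_presences_in_background = include_presences_in_background
        self.max_iter = max_iter
        self.tol = tol

    # -- core fit ----------------------------------------------------------
    def fit(self, X, y) -> "MaxentSDM":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if self.beta_multiplier < 0:
            raise InvalidParameterError("beta_multiplier must be >= 0")
        if X.ndim != 2 or len(X) != len(y):
            raise SchemaError("X must be 2-D with one label per row")
        pres = X[y == 1]
        bg = X[y == 0]
        if len(pres) < 5:
            raise TooFewRecordsError(
                f"need at least 5 presence rows, got {len(pres)}"
            )
        if len(bg) == 0:
            raise InvalidParameterError("background sample is empty")
        if self.include_presences_in_background:
            bg = np.vstack([bg, pres])

        n_var = X.shape[1]
        var_names = tuple(
            BIOCLIM_VARS[i] if n_var == len(BIOCLIM_VARS) else f"x{i}" for i in range(n_var)
        )
        fs = FeatureSpace(variable_names=var_names).fit(bg)
        F_bg_full = fs.transform(bg)
        F_pres_full = fs.transform(pres)
        m = len(F_pres_full)
        n_feat_full = F_bg_full.shape[1]

        # prune degenerate features: (near-)constant on background, or
        # near-duplicates of an earlier feature (e.g. a product with a
        # variable that barely varies); they carry no information and make
        # the optimization valley flat
        sd_full = F_bg_full.std(axis=0)
        keep = np.zeros(n_feat_full, dtype=bool)
        centered = F_bg_full - F_bg_full.mean(axis=0)
        for j in range(n_feat_full):
            if sd_full[j] < 1e-9:
                continue
            dup = False
            for k in np.nonzero(keep)[0]:
                corr = (centered[:, j] @ centered[:, k]) / (len(centered) * sd_full[j] * sd_full[k])
                if abs(corr) > 0.999:
                    dup = True
                    break
            keep[j] = not dup

        F_bg = F_bg_full[:, keep]
        F_pres = F_pres_full[:, keep]
        p_mean = F_pres.mean(axis=0)
        sd_bg = F_bg.std(axis=0)
        beta = self.beta_multiplier * sd_bg / np.sqrt(m)

        n_feat = F_bg.shape[1]

        def smooth(lam: np.ndarray) -> tuple[float, np.ndarray]:
            # logZ - mean_pres(lam . f), with gradient E_raw[f] - p_mean
            scores = F_bg @ lam
            log_z = logsumexp(scores)
            w = np.exp(scores - log_z)
            return log_z - p_mean @ lam, F_bg.T @ w - p_mean

        def solve(beta_eff: np.ndarray, x0: np.ndarray):
            def objective(ab: np.ndarray) -> tuple[float, np.ndarray]:
                a, b = ab[:n_feat], ab[n_feat:]
                val, g = smooth(a - b)
                val += beta_eff @ (a + b)
                return val, np.concatenate([g + beta_eff, -g + beta_eff])

            return minimize(
                objective,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=[(0.0, None)] * (2 * n_feat),
                options={"maxiter": self.max_iter, "ftol": 1e-15, "gtol": 1e-10,
                         "maxcor": 50, "maxls": 100},
            )

        def min_norm_subgrad(lam: np.ndarray) -> float:
            _, g = smooth(lam)
            sub = np.where(
                lam > 0, g + beta,
                np.where(lam < 0, g - beta,
                         np.sign(g) * np.maximum(np.abs(g) - beta, 0.0)),
            )
            return float(np.max(np.abs(sub))) if n_feat else 0.0

        def penalized(lam: np.ndarray) -> float:
            val, _ = smooth(lam)
            return val + beta @ np.abs(lam)

        def grad_hess(lam: np.ndarray):
            scores = F_bg @ lam
            w = np.exp(scores - logsumexp(scores))
            mu = F_bg.T @ w
            g = mu - p_mean
            H = (F_bg * w[:, None]).T @ F_bg - np.outer(mu, mu)
            return g, H

        def _quadratic_l1_direction(lam, g, H, sweeps=60):
            # inner solver of the proximal-Newton subproblem
            #   min_u  g.(u-lam) + 1/2 (u-lam)' H (u-lam) + beta.|u|
            # by cyclic coordinate descent with closed-form soft-threshold
            # updates (the glmnet/QUIC construction)
            u = lam.copy()
            Hdelta = np.zeros_like(lam)  # H @ (u - lam)
            diag = np.diag(H)
            for _ in range(sweeps):
                max_move = 0.0
                for j in range(len(lam)):
                    a = diag[j]
                    if a <= 1e-14:
                        continue
                    c = g[j] + Hdelta[j] - a * (u[j] - lam[j])
                    z = a * lam[j] - c
                    u_new = np.sign(z) * max(abs(z) - beta[j], 0.0) / a
                    delta = u_new - u[j]
                    if delta != 0.0:
                        Hdelta += H[:, j] * delta
                        u[j] = u_new
                        max_move = max(max_move, abs(delta))
                if max_move < 1e-13:
                    break
            return u - lam

        def newton_polish(lam: np.ndarray) -> np.ndarray:
            # proximal Newton: the smooth Hessian is tiny (n_feat^2), so
            # exact second-order steps resolve the flat, ill-conditioned
            # valley that stalls first-order methods under weak L1 penalties
            lam = lam.copy()
            tol = max(self.tol, 1e-8)
            for _ in range(100):
                if min_norm_subgrad(lam) <= tol:
                    break
                g, H = grad_hess(lam)
                d = _quadratic_l1_direction(lam, g, H)
                if np.max(np.abs(d)) < 1e-13:
                    break
                base_val = penalized(lam)
                step = 1.0
                for _ls in range(30):
                    trial = lam + step * d
                    if penalized(trial) < base_val:
                        lam = trial
                        break
                    step *= 0.5
                else:
                    break  # no descent along the subproblem direction
            return lam

        # warm start with a strongly regularized (well-conditioned) solve,
        # then continue toward the requested penalty and polish
        x0 = np.zeros(2 * n_feat)
        sd_scale = sd_bg / np.sqrt(m)
        schedule = [b for b in (0.5, 0.1) if b > self.beta_multiplier]
        schedule.append(self.beta_multiplier)
        for mult in schedule:
            res = solve(mult * sd_scale, x0)
            x0 = res.x
        lam = newton_polish(res.x[:n_feat] - res.x[n_feat:])
        sub_norm = min_norm_subgrad(lam)
        if sub_norm > 1e-3:
            raise ConvergenceError(
                f"maxent fit did not converge: subgradient inf-norm {sub_norm:.3e}"
            )

        scores = F_bg @ lam
        log_z = logsumexp(scores)
        log_p = scores - log_z
        p = np.exp(log_p)

        lam_full = np.zeros(n_feat_full)
        lam_full[keep] = lam
        beta_full = self.beta_multiplier * sd_full / np.sqrt(m)

        self.classes_ = np.array([0, 1])
        self.n_features_in_ = n_var
        self.feature_space_ = fs
        self.lambda_ = lam_full
        self.beta_ = beta_full
        self.feature_kept_ = keep
        self.log_z_ = float(log_z)
        self.entropy_ = float(-(p @ log_p))
        self.n_background_ = len(F_bg)
        self.subgradient_norm_ = sub_norm
        self.objective_ = float(-res.fun)
        return self

    # -- prediction --------------------------------------------------------
    def _log_raw(self, X) -> np.ndarray:
        check_is_fitted(self, "lambda_")
        F = self.feature_space_.transform(np.asarray(X, dtype=np.float64))
        return F @ self.lambda_ - self.log_z_

    def raw(self, X) -> np.ndarray:
        """Gibbs probability relative to the background partition sum."""
        return np.exp(self._log_raw(X))

    def decision_function(self, X) -> np.ndarray:
        """Log-odds of the logistic suitability output."""
        return self.entropy_ + self._log_raw(X)

    def predict_logistic(self, X) -> np.ndarray:
        """Logistic suitability in (0, 1): eH*raw / (1 + eH*raw)."""
        return expit(self.decision_function(X))

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.predict_logistic(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_logistic(X) >= 0.5).astype(int)

    def score(self, X, y) -> float:
        """Presence-vs-background AUC of the logistic output."""
        return float(roc_auc_score(y, self.predict_logistic(X)))

    # -- serialization -----------------------------------------------------
    def to_json_dict(self) -> dict:
        check_is_fitted(self, "lambda_")
        d = {
            "params": self.get_params(),
            "variables": list(self.feature_space_.variable_names),
            "feature_names": self.feature_space_.feature_names,
            "f_min": self.feature_space_.f_min.tolist(),
            "f_max": self.feature_space_.f_max.tolist(),
            "lambda": self.lambda_.tolist(),
            "beta": self.beta_.tolist(),
            "log_z": self.log_z_,
            "entropy": self.entropy_,
            "n_background": self.n_background_,
        }
        for opt in ("auc_", "threshold_logistic_", "species_id_"):
            if hasattr(self, opt):
                d[opt.rstrip("_")] = getattr(self, opt)
        if hasattr(self, "presence_cells_"):
            d["presence_cells"] = [list(c) for c in self.presence_cells_]
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "MaxentSDM":
        model = cls(**d["params"])
        fs = FeatureSpace(variable_names=tuple(d["variables"]))
        fs.feature_names = list(d["feature_names"])
        fs.f_min = np.asarray(d["f_min"], dtype=np.float64)
        fs.f_max = np.asarray(d["f_max"], dtype=np.float64)
        model.feature_space_ = fs
        model.lambda_ = np.asarray(d["lambda"], dtype=np.float64)
        model.beta_ = np.asarray(d["beta"], dtype=np.float64)
        model.log_z_ = float(d["log_z"])
        model.entropy_ = float(d["entropy"])
        model.n_background_ = int(d["n_background"])
        model.classes_ = np.array([0, 1])
        model.n_features_in_ = len(d["variables"])
        for opt in ("auc", "threshold_logistic", "species_id"):
            if opt in d:
                setattr(model, opt + "_", d[opt])
        if "presence_cells" in d:
            model.presence_cells_ = [tuple(c) for c in d["presence_cells"]]
        return model

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load_json(cls, path) -> "MaxentSDM":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


@dataclass
class SuitabilityMap:
    """Continuous (0,1) suitability raster with provenance."""

    values: np.ndarray
    grid: GridSpec
    species_id: str = "sp"
    provenance: str = "baseline"


def build_background(
    stack: ClimateStack, n_background: int = 10_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly sample background cells (without replacement) from the stack.

    Returns (rows, cols) index arrays.  When the landscape holds fewer valid
    cells than requested, every valid cell is used and a notice is emitted.
    """
    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    n_valid = len(rows)
    if n_valid == 0:
        raise InvalidParameterError("climate stack has no valid cells")
    if n_background >= n_valid:
        if n_background > n_valid:
            warnings.warn(
                f"requested {n_background} background points but only "
                f"{n_valid} valid cells; using all cells",
                stacklevel=2,
            )
        return rows, cols
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_valid, size=n_background, replace=False)
    pick.sort()
    return rows[pick], cols[pick]


def fit_species(
    occurrences,
    stack: ClimateStack,
    background: tuple[np.ndarray, np.ndarray],
    species_id: str = "sp",
    **params,
) -> MaxentSDM:
    """Fit a maxent model for one species from occurrence points.

    Occurrence records (DataFrame with x, y columns) are deduplicated to one
    presence per cell before fitting; at least 5 unique presence cells are
    required.  ``background`` is the (rows, cols) sample from
    :func:`build_background`.
    """
    cells = set()
    for x, y in zip(occurrences["x"].to_numpy(), occurrences["y"].to_numpy()):
        cell = stack.grid.point_to_cell(float(x), float(y))
        if cell is not None:
            cells.add(cell)
    mask = stack.valid_mask()
    cells = sorted(c for c in cells if mask[c])
    if len(cells) < 5:
        raise TooFewRecordsError(
            f"species {species_id!r}: {len(cells)} unique presence cells (< 5)"
        )
    pres_rows = np.array([c[0] for c in cells])
    pres_cols = np.array([c[1] for c in cells])
    arr = stack.to_array()
    X_pres = arr[:, pres_rows, pres_cols].T
    X_bg = arr[:, background[0], background[1]].T
    X = np.vstack([X_pres, X_bg])
    y = np.concatenate([np.ones(len(X_pres), dtype=int), np.zeros(len(X_bg), dtype=int)])
    model = MaxentSDM(**params).fit(X, y)
    model.species_id_ = species_id
    model.presence_cells_ = cells
    model.auc_ = float(model.score(X, y))
    return model


def predict_logistic(model: MaxentSDM, stack: ClimateStack, provenance: str = "baseline") -> SuitabilityMap:
    """Predict logistic suitability over a climate stack (NaN stays nodata)."""
    for v in model.feature_space_.variable_names:
        if getattr(stack, v, None) is None:
            raise SchemaError(f"stack is missing model variable {v!r}")
    mask = stack.valid_mask()
    out = np.full(stack.grid.shape, np.nan)
    X = stack.to_matrix(mask)
    out[mask] = model.predict_logistic(X)
    return SuitabilityMap(
        values=out,
        grid=stack.grid,
        species_id=getattr(model, "species_id_", "sp"),
        provenance=provenance,
    )


def auc_score(presence_scores, background_scores) -> float:
    """Presence-vs-background AUC (Mann-Whitney; ties count one half)."""
    presence_scores = np.asarray(presence_scores, dtype=np.float64)
    background_scores = np.asarray(background_scores, dtype=np.float64)
    if presence_scores.size == 0 or background_scores.size == 0:
        raise InvalidParameterError("both score sets must be nonempty")
    y = np.concatenate([np.ones(presence_scores.size), np.zeros(background_scores.size)])
    s = np.concatenate([presence_scores, background_scores])
    return float(roc_auc_score(y, s))


def screen(models: dict, threshold: float = 0.7) -> tuple[dict, dict]:
    """Split models into (kept, excluded) by the AUC screening rule.

    Models with AUC >= threshold are kept for species-level analyses;
    excluded models are retained so richness stacking can still include
    every species.
    """
    kept, excluded = {}, {}
    for sid, model in models.items():
        (kept if model.auc_ >= threshold else excluded)[sid] = model
    return kept, excluded


def entropy_equating_threshold(model: MaxentSDM, baseline_map: SuitabilityMap) -> float:
    """Logistic threshold equating the entropy of thresholded and fitted distributions.

    A uniform distribution over k cells has entropy log(k); the rule keeps
    the k = round(exp(H)) highest-suitability cells of the baseline
    landscape, where H is the entropy of the fitted raw distribution, and
    returns the k-th largest logistic value as the species-specific
    threshold (computed once on the baseline and reused for all future
    projections).
    """
    vals = baseline_map.values[np.isfinite(baseline_map.values)]
    if vals.size == 0:
        raise InvalidParameterError("baseline suitability map has no valid cells")
    k = entropy_matching_count(model.entropy_, vals.size)
    vals_sorted = np.sort(vals)[::-1]
    thr = float(vals_sorted[k - 1])
    model.threshold_logistic_ = thr
    return thr


def entropy_matching_count(entropy: float, n: int) -> int:
    """The cell count k in [1, n] whose uniform entropy log(k) is closest to H."""
    k = int(np.clip(np.floor(np.exp(entropy)), 1, n))
    if k + 1 <= n and abs(np.log(k + 1) - entropy) < abs(np.log(k) - entropy):
        k += 1
    return k
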