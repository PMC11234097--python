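"""NIPALS partial least squares regression for single-response calibration.

Implements the classical sequential NIPALS factorization on mean-centered
predictors and response (no variance scaling): for each component the
weight vector w = X'y / ||X'y|| defines scores t = Xw, X is deflated by the
rank-one approximation t p', and the response loading q = y't / t't is
accumulated.  For a single response y-deflation is redundant and omitted.
The factorization is collapsed to a regression-coefficient vector

    b = W (P'W)^{-1} q,    intercept = y_mean - x_mean . b

so prediction is the affine map X b + intercept.  Model selection follows
leave-one-out cross-validation of the RMSECV curve; validation quality is
summarized by RMSEP, the relative error RE = RMSEP / mean(y_obs), and R^2
as the squared Pearson correlation of observed vs predicted values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .spectra import ReferenceTable, SpectraSet, SpectraError


def _nipals(Xc: np.ndarray, yc: np.ndarray, k: int):
    """Sequential NIPALS on centered data; returns (W, P, q).

    Stops early (returning fewer than k factors) when the deflated predictor
    matrix no longer covaries with the response, i.e. the problem's rank is
    exhausted — further factors would be numerical noise.
    """
    n, m = Xc.shape
    W = np.empty((m, k))
    P = np.empty((m, k))
    q = np.empty(k)
    Xd = Xc.copy()
    x_scale = np.linalg.norm(Xc) * max(np.linalg.norm(yc), 1.0)
    extracted = 0
    for a in range(k):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(x_scale, 1e-300):
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt <= 0.0:
            break
        p = Xd.T @ t / tt
        W[:, a] = w
        P[:, a] = p
        q[a] = (yc @ t) / tt
        Xd -= np.outer(t, p)
        extracted += 1
    if extracted == 0:
        raise np.linalg.LinAlgError("no PLS component could be extracted")
    return W[:, :extracted], P[:, :extracted], q[:extracted]


def _coef_from_factors(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


class NipalsPLS(RegressorMixin, BaseEstimator):
    """Single-response PLS regression via NIPALS with mean centering only.

    Parameters
    ----------
    n_components : int
        Number of latent variables to extract.

    Attributes
    ----------
    x_mean_, y_mean_ : centering applied before factorization.
    x_weights_, x_loadings_ : (n_features, n_components) W and P matrices.
    y_loadings_ : (n_components,) response loadings q.
    coef_, intercept_ : collapsed regression vector and offset; predictions
        via the factorization and via (coef_, intercept_) agree to 1e-10.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, m = X.shape
        if y.size != n:
            raise ValueError("X and y have incompatible lengths")
        k = int(self.n_components)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if k > min(n - 1, m):
            raise ValueError(
                f"n_components={k} exceeds min(n_samples-1, n_features)="
                f"{min(n - 1, m)}"
            )
        if np.ptp(y) == 0.0:
            raise ValueError("response has zero variance")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        self.x_weights_, self.x_loadings_, self.y_loadings_ = _nipals(Xc, yc, k)
        self.n_components_ = self.x_weights_.shape[1]  # may be < k at low rank
        self.coef_ = _coef_from_factors(
            self.x_weights_, self.x_loadings_, self.y_loadings_,
            self.n_components_,
        )
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        self.n_features_in_ = m
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.coef_.size:
            raise ValueError(
                f"X has {X.shape[-1]} features, model expects {self.coef_.size}"
            )
        return X @ self.coef_ + self.intercept_


@dataclass(frozen=True)
class CVResult:
    """RMSECV curve over component counts and the selected count."""

    rmsecv_by_k: np.ndarray
    chosen_k: int


@dataclass(frozen=True)
class PredictionMetrics:
    """Validation-set summary in the response's units (%DW for RMSEP)."""

    rmsep: float
    re: float
    r2: float
    n_val: int


def fit_pls(X, y, k: int) -> NipalsPLS:
    """Fit a k-component NIPALS PLS model (thin wrapper over NipalsPLS)."""
    return NipalsPLS(n_components=k).fit(X, y)


def predict(model: NipalsPLS, X) -> np.ndarray:
    return model.predict(X)


def loo_cv_select(X, y, k_max: int) -> CVResult:
    """Leave-one-out RMSECV for k = 1..k_max; chosen_k = argmin (first on ties).

    One NIPALS factorization at k_max per left-out sample suffices: NIPALS
    components are nested, so the k-component coefficient vector is read off
    the leading k factors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 5:
        raise ValueError("leave-one-out selection needs n >= 5")
    if k_max > n - 2:
        raise ValueError("k_max must be <= n - 2")
    preds = np.empty((n, k_max))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xi, yi = X[keep], y[keep]
        xm, ym = Xi.mean(axis=0), yi.mean()
        W, P, q = _nipals(Xi - xm, yi - ym, k_max)
        avail = W.shape[1]
        for k in range(1, k_max + 1):
            b = _coef_from_factors(W, P, q, min(k, avail))
            preds[i, k - 1] = (X[i] - xm) @ b + ym
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    return CVResult(rmsecv_by_k=rmsecv, chosen_k=int(np.argmin(rmsecv)) + 1)


def prediction_metrics(y_obs, y_pred) -> PredictionMetrics:
    """RMSEP, RE = RMSEP/mean(y_obs), and R^2 as squared Pearson correlation.

    R^2 is floored at 0 for zero-variance predictions (a failed model's
    constant output has no linear association with the observations).
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size != y_pred.size:
        raise ValueError("observed and predicted lengths differ")
    if y_obs.size < 2:
        raise ValueError("need at least 2 validation samples")
    rmsep = float(np.sqrt(np.mean((y_pred - y_obs) ** 2)))
    mean_obs = float(np.mean(y_obs))
    if mean_obs <= 0:
        raise ValueError("mean observed value must be > 0 for RE")
    if np.ptp(y_pred) == 0.0 or np.ptp(y_obs) == 0.0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)
    return PredictionMetrics(rmsep=rmsep, re=rmsep / mean_obs, r2=r2,
                             n_val=int(y_obs.size))


def split_calibration_validation(
    s: SpectraSet,
    ref: ReferenceTable,
    frac: float = 0.75,
    seed: int = 0,
) -> tuple[tuple[SpectraSet, np.ndarray], tuple[SpectraSet, np.ndarray]]:
    """Deterministic calibration/validation split stratified over y-quartiles.

    Calibration receives round(frac * n) samples.  Samples are binned by the
    rank of their reference value into four quartile bins and validation
    picks are spread across bins proportionally (largest remainder), so the
    validation range is covered by the calibration range.

    Returns ``((cal_spectra, y_cal), (val_spectra, y_val))``.
    """
    if not 0.5 < frac < 0.95:
        raise ValueError("frac must lie in (0.5, 0.95)")
    y = ref.align(s)
    n = y.size
    if n < 8:
        raise ValueError("need at least 8 samples to split")
    n_cal = int(round(frac * n))
    n_val = n - n_cal
    rank = np.argsort(np.argsort(y, kind="stable"), kind="stable")
    bins = np.minimum((4 * rank) // n, 3)
    sizes = np.bincount(bins, minlength=4)
    quota = n_val * sizes / n
    take = np.floor(quota).astype(int)
    rem = np.argsort(-(quota - take), kind="stable")
    for b in rem[: n_val - take.sum()]:
        take[b] += 1
    rng = np.random.default_rng(seed)
    # the y-extremes stay in calibration so validation never extrapolates
    anchors = {int(np.argmin(y)), int(np.argmax(y))}
    val_idx: list[int] = []
    deficit = 0
    for b in range(4):
        pool = [i for i in np.flatnonzero(bins == b) if i not in anchors]
        want = min(take[b], len(pool))
        deficit += take[b] - want
        val_idx.extend(rng.choice(pool, size=want, replace=False))
    if deficit:  # redistribute picks lost to anchor exclusion
        spare = [i for i in range(n)
                 if i not in val_idx and i not in anchors]
        val_idx.extend(rng.choice(spare, size=deficit, replace=False))
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    cal_i = np.flatnonzero(~val_mask)
    val_i = np.flatnonzero(val_mask)
    return (s.select(cal_i), y[cal_i]), (s.select(val_i), y[val_i])


# ---------------------------------------------------------------------------
# grid-aware model bundle with JSON serialization
# ---------------------------------------------------------------------------


@dataclass
class PLSModelBundle:
    """A fitted NipalsPLS bound to the wavenumber grid it was trained on."""

    model: NipalsPLS
    grid: np.ndarray
    chosen_k: int
    seed: int | None = None

    def predict_spectra(self, s: SpectraSet) -> np.ndarray:
        if len(s.grid) != self.grid.size or not np.allclose(
            s.grid.values, self.grid, rtol=1e-9, atol=1e-9
        ):
            raise SpectraError("spectra grid does not match model grid")
        return self.model.predict(s.absorbance)

    def to_json(self, path) -> None:
        m = self.model
        payload = {
            "schema": "driftfa-pls-model/1",
            "grid": self.grid.tolist(),
            "n_components": int(m.n_components),
            "chosen_k": int(self.chosen_k),
            "seed": self.seed,
            "x_mean": m.x_mean_.tolist(),
            "y_mean": m.y_mean_,
            "x_weights": m.x_weights_.tolist(),
            "x_loadings": m.x_loadings_.tolist(),
            "y_loadings": m.y_loadings_.tolist(),
            "coef": m.coef_.tolist(),
            "intercept": m.intercept_,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PLSModelBundle":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        m = NipalsPLS(n_components=int(payload["n_components"]))
        m.x_mean_ = np.asarray(payload["x_mean"], dtype=float)
        m.y_mean_ = float(payload["y_mean"])
        m.x_weights_ = np.asarray(payload["x_weights"], dtype=float)
        m.x_loadings_ = np.asarray(payload["x_loadings"], dtype=float)
        m.y_loadings_ = np.asarray(payload["y_loadings"], dtype=float)
        m.coef_ = np.asarray(payload["coef"], dtype=float)
        m.intercept_ = float(payload["intercept"])
        m.n_features_in_ = m.coef_.size
        return cls(
            model=m,
            grid=np.asarray(payload["grid"], dtype=float),
            chosen_k=int(payload["chosen_k"]),
            seed=payload.get("seed"),
        )
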