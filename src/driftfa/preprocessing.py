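"""Spectral pretreatment: fingerprint-region cut, asymmetric least squares
(AsLS) baseline correction, and normalization to unit total spectral area.

The AsLS baseline follows the Eilers-Boelens penalized-least-squares
formulation: the baseline z minimizes

    sum_i w_i (y_i - z_i)^2  +  lam * sum_i (Delta^2 z)_i^2

with asymmetric weights w_i = p where y_i > z_i and 1 - p otherwise,
iterated from w = 1.  Points above the running baseline (peaks) are
down-weighted by the small asymmetry p, so z tracks the lower envelope while
the second-difference penalty keeps it smooth.  Defaults lam = 20000,
p = 0.001 suit fingerprint-region biomass spectra on a 4 cm^-1 grid.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import SpectraSet, SpectraError


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the pretreatment chain.

    region_lo/region_hi bound the retained fingerprint window in cm^-1
    (closed interval); asls_lambda is the smoothness penalty, asls_p the
    asymmetry weight given to points above the baseline.
    """

    region_lo: float = 800.0
    region_hi: float = 1800.0
    asls_lambda: float = 20_000.0
    asls_p: float = 0.001
    asls_max_iter: int = 50
    asls_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.region_lo < self.region_hi:
            raise ValueError("region_lo must be < region_hi")
        if not self.asls_lambda > 0:
            raise ValueError("asls_lambda must be > 0")
        if not 0.0 < self.asls_p < 1.0:
            raise ValueError("asls_p must be in (0, 1)")
        if self.asls_max_iter < 1:
            raise ValueError("asls_max_iter must be >= 1")


def cut_region(s: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Retain grid points in the closed interval [lo, hi]."""
    mask = s.grid.window_mask(lo, hi)
    if not mask.any():
        raise SpectraError(f"region [{lo:g}, {hi:g}] outside grid")
    from .spectra import WavenumberGrid

    out = SpectraSet(
        WavenumberGrid(s.grid.values[mask]),
        s.absorbance[:, mask],
        list(s.sample_ids),
        s.metadata,
        list(s.provenance),
    )
    out.provenance.append({"step": "cut_region", "lo": lo, "hi": hi})
    return out


def asls_baseline(
    y: np.ndarray,
    lam: float = 20_000.0,
    p: float = 0.001,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Asymmetric least squares baseline of a single spectrum.

    Returns ``(baseline, corrected)`` with ``corrected = y - baseline``,
    not floored at zero.  Iteration stops at an exact fixed point of the
    asymmetric weight assignment, when the relative change in the baseline
    falls below ``tol``, or after ``max_iter`` reweightings.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("signal must be 1-D with at least 3 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in signal")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    n = y.size
    # second-order difference operator, (n-2) x n
    D = sparse.diags_array(
        [np.ones(n - 2), -2.0 * np.ones(n - 2), np.ones(n - 2)],
        offsets=[0, 1, 2],
        shape=(n - 2, n),
    )
    penalty = (lam * (D.T @ D)).tocsc()
    w = np.ones(n)
    z = y.copy()
    for _ in range(max_iter):
        A = sparse.diags_array(w, offsets=0, shape=(n, n), format="csc") + penalty
        z_new = spsolve(A, w * y)
        w_new = np.where(y > z_new, p, 1.0 - p)
        z_change = np.max(np.abs(z_new - z)) / max(np.max(np.abs(z_new)), 1e-300)
        z = z_new
        if np.array_equal(w_new, w) or z_change < tol:
            break
        w = w_new
    return z, y - z


def area_normalize(s: SpectraSet) -> SpectraSet:
    """Scale each spectrum so its trapezoidal integral over the grid is 1.

    Scaling factors (the original areas) are recorded in provenance.
    """
    areas = np.trapezoid(s.absorbance, s.grid.values, axis=1)
    if (areas <= 0).any():
        bad = s.sample_ids[int(np.argmax(areas <= 0))]
        raise SpectraError(f"non-positive spectral area for sample {bad!r}")
    out = SpectraSet(
        s.grid,
        s.absorbance / areas[:, None],
        list(s.sample_ids),
        s.metadata,
        list(s.provenance),
    )
    out.provenance.append(
        {"step": "area_normalize", "areas": {i: float(a) for i, a in zip(s.sample_ids, areas)}}
    )
    return out


class AslsBaseline(TransformerMixin, BaseEstimator):
    """Stateless per-spectrum AsLS baseline-correction transformer.

    Parameters
    ----------
    lam : smoothness penalty (larger -> stiffer baseline).
    p : asymmetry weight for points above the baseline, in (0, 1).
    """

    def __init__(self, lam: float = 20_000.0, p: float = 0.001,
                 max_iter: int = 50, tol: float = 1e-6):
        self.lam = lam
        self.p = p
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        for i, row in enumerate(X):
            _, out[i] = asls_baseline(row, self.lam, self.p, self.max_iter, self.tol)
        return out


class SpectralPreprocessor(TransformerMixin, BaseEstimator):
    """Full pretreatment chain on a :class:`SpectraSet`:

    cut to [region_lo, region_hi] -> AsLS baseline per spectrum ->
    normalization to unit trapezoidal area.  ``transform`` accepts and
    returns a SpectraSet; the applied config is attached to provenance.
    """

    def __init__(self, config: PreprocessConfig | None = None):
        self.config = config

    def _cfg(self) -> PreprocessConfig:
        return self.config if self.config is not None else PreprocessConfig()

    def fit(self, X: SpectraSet, y=None):
        cfg = self._cfg()
        self.config_ = cfg
        self.mask_ = X.grid.window_mask(cfg.region_lo, cfg.region_hi)
        if not self.mask_.any():
            raise SpectraError(
                f"region [{cfg.region_lo:g}, {cfg.region_hi:g}] outside grid"
            )
        return self

    def transform(self, X: SpectraSet) -> SpectraSet:
        cfg = self.config_
        s = cut_region(X, cfg.region_lo, cfg.region_hi)
        corrected = np.empty_like(s.absorbance)
        iterations: dict[str, int] = {}
        for i, row in enumerate(s.absorbance):
            _, corrected[i] = asls_baseline(
                row, cfg.asls_lambda, cfg.asls_p, cfg.asls_max_iter, cfg.asls_tol
            )
        s = SpectraSet(s.grid, corrected, list(s.sample_ids), s.metadata,
                       list(s.provenance))
        s.provenance.append({"step": "asls_baseline", **asdict(cfg)})
        s = area_normalize(s)
        s.provenance.append({"step": "preprocess_pipeline", "config": asdict(cfg)})
        return s

    def fit_transform(self, X: SpectraSet, y=None, **kwargs) -> SpectraSet:
        return self.fit(X).transform(X)


def preprocess_pipeline(s: SpectraSet, cfg: PreprocessConfig | None = None) -> SpectraSet:
    """Cut -> AsLS -> area-normalize with the given configuration."""
    return SpectralPreprocessor(cfg).fit_transform(s)
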