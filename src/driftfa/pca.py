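"""Principal component analysis of preprocessed spectra.

SVD-based PCA on mean-centered absorbance with a deterministic sign
convention (the largest-magnitude element of each loading vector is made
positive), plus per-group score summaries with 90 % normal-theory
confidence ellipses in the (PC1, PC2) plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import SpectraSet


class SpectraPCA(TransformerMixin, BaseEstimator):
    """PCA via SVD of the centered spectra matrix.

    Attributes
    ----------
    mean_ : mean spectrum removed before decomposition.
    components_ : (n_components, n_features) orthonormal loading rows.
    explained_variance_ : per-component score variance (ddof=1).
    explained_variance_ratio_ : fraction of total variance, non-increasing.
    scores_ : (n_samples, n_components) scores of the training samples.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        k = int(self.n_components)
        if not 1 <= k <= min(n - 1, m):
            raise ValueError(
                f"n_components={k} must be in [1, min(n_samples-1, n_features)="
                f"{min(n - 1, m)}]"
            )
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        # deterministic sign: largest-|.| loading element positive
        for a in range(Vt.shape[0]):
            j = int(np.argmax(np.abs(Vt[a])))
            if Vt[a, j] < 0:
                Vt[a] *= -1.0
                U[:, a] *= -1.0
        var_all = s**2 / (n - 1)
        self.components_ = Vt[:k]
        self.singular_values_ = s[:k]
        self.explained_variance_ = var_all[:k]
        self.explained_variance_ratio_ = var_all[:k] / var_all.sum()
        self.scores_ = U[:, :k] * s[:k]
        self.n_features_in_ = m
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, T):
        return np.asarray(T, dtype=float) @ self.components_ + self.mean_


def fit_pca(X, n_components: int) -> SpectraPCA:
    """Fit PCA on a preprocessed spectra matrix (thin wrapper)."""
    X = X.absorbance if isinstance(X, SpectraSet) else X
    return SpectraPCA(n_components=n_components).fit(X)


def cumulative_variance(m: SpectraPCA, k: int) -> float:
    """Fraction of total variance explained by the first k components."""
    if k == 0:
        return 0.0
    if k > m.explained_variance_ratio_.size:
        raise ValueError("k exceeds fitted component count")
    return float(m.explained_variance_ratio_[:k].sum())


@dataclass(frozen=True)
class GroupEllipse:
    """Centroid and 90 % confidence ellipse of one group in (PC1, PC2)."""

    label: str
    n: int
    centroid: np.ndarray
    covariance: np.ndarray | None  # None when n < 3
    semi_axes: np.ndarray | None  # major, minor
    angle_deg: float | None  # orientation of the major axis


CHI2_90_2DF = float(stats.chi2.ppf(0.90, df=2))


def _ellipse(label: str, pts: np.ndarray) -> GroupEllipse:
    centroid = pts.mean(axis=0)
    if pts.shape[0] < 3:
        return GroupEllipse(label, pts.shape[0], centroid, None, None, None)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    semi = np.sqrt(np.maximum(evals, 0.0) * CHI2_90_2DF)
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return GroupEllipse(label, pts.shape[0], centroid, cov, semi, angle)


def _ellipse_boundary(e: GroupEllipse, n_pts: int = 256) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n_pts, endpoint=False)
    a, b = e.semi_axes
    ang = np.radians(e.angle_deg)
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    xy = np.stack([a * np.cos(th), b * np.sin(th)])
    return (R @ xy).T + e.centroid


def _inside(e: GroupEllipse, pts: np.ndarray) -> np.ndarray:
    d = pts - e.centroid
    cov = e.covariance * CHI2_90_2DF
    sol = np.linalg.solve(cov, d.T).T
    return np.einsum("ij,ij->i", d, sol) <= 1.0


def ellipses_overlap(e1: GroupEllipse, e2: GroupEllipse) -> bool:
    """Whether two 90 % ellipses intersect (boundary-sampling test)."""
    if e1.semi_axes is None or e2.semi_axes is None:
        return False
    if _inside(e2, e1.centroid[None])[0] or _inside(e1, e2.centroid[None])[0]:
        return True
    return bool(
        _inside(e2, _ellipse_boundary(e1)).any()
        or _inside(e1, _ellipse_boundary(e2)).any()
    )


def score_group_summary(
    m: SpectraPCA, groups: pd.Series | np.ndarray
) -> dict:
    """Per-group centroid and 90 % confidence ellipse in the (PC1, PC2) plane.

    Groups with fewer than 3 samples get a centroid only.  The summary also
    lists pairs of groups whose ellipses do not intersect.
    """
    labels = pd.Series(np.asarray(groups), dtype="object")
    if labels.size != m.scores_.shape[0]:
        raise ValueError("group labels must match fitted sample count")
    pts = m.scores_[:, :2]
    ellipses = {
        str(lab): _ellipse(str(lab), pts[(labels == lab).to_numpy()])
        for lab in labels.dropna().unique()
    }
    names = sorted(ellipses)
    disjoint = [
        (a, b)
        for i, a in enumerate(names)
        for b in names[i + 1:]
        if ellipses[a].semi_axes is not None
        and ellipses[b].semi_axes is not None
        and not ellipses_overlap(ellipses[a], ellipses[b])
    ]
    return {"groups": ellipses, "disjoint_pairs": disjoint}
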