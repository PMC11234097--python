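"""Univariate comparator: peak heights at single marker bands and their
ratio, with simple ordinary-least-squares calibration against fatty acid
content.

The lipid ester carbonyl stretch near 1740-1750 cm^-1 is the principal
fatty-acid marker; the protein Amide I band near 1650 cm^-1 serves as the
ratio denominator.  Heights are the maximum absorbance within a small
closed window around the nominal center, absorbing the +-10 cm^-1
ambiguity of literature band positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra import SpectraSet


@dataclass(frozen=True)
class PeakDefinition:
    """Nominal band center and half-window, both in cm^-1."""

    center: float
    half_window: float = 8.0


ESTER_CARBONYL = PeakDefinition(center=1740.0)
AMIDE_I = PeakDefinition(center=1650.0)


def peak_height(spec: SpectraSet, pk: PeakDefinition) -> np.ndarray:
    """Maximum absorbance within [center - hw, center + hw], per sample."""
    if pk.half_window < spec.grid.spacing:
        raise ValueError("half_window must be >= grid spacing")
    mask = spec.grid.window_mask(pk.center - pk.half_window, pk.center + pk.half_window)
    if not mask.any():
        raise ValueError(
            f"peak window around {pk.center:g} cm^-1 lies outside the grid"
        )
    return spec.absorbance[:, mask].max(axis=1)


def peak_ratio(
    spec: SpectraSet,
    pk_num: PeakDefinition = ESTER_CARBONYL,
    pk_den: PeakDefinition = AMIDE_I,
) -> np.ndarray:
    """height(pk_num) / height(pk_den) per sample; zero denominators raise."""
    num = peak_height(spec, pk_num)
    den = peak_height(spec, pk_den)
    if (den <= 0).any():
        bad = spec.sample_ids[int(np.argmax(den <= 0))]
        raise ValueError(f"non-positive denominator peak for sample {bad!r}")
    return num / den


def univariate_calibration(x, y) -> dict:
    """OLS line y = slope*x + intercept with squared Pearson r^2."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0.0:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
    }
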