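"""Seeded generator of DRIFTS-like microalgal spectra with known fatty-acid
ground truth.

Each sample is a Beer-Lambert-style linear mixture of component spectra
(fatty acid, protein, carbohydrate, broad background) built from Gaussian /
Lorentzian bands at literature positions — the lipid ester carbonyl at
1740 cm^-1, Amide I/II at 1650/1540 cm^-1, carbohydrate C-O-C stretches in
the 950-1200 cm^-1 region — plus a smooth random baseline, a multiplicative
log-normal gain (scatter / effective path length), mineral-ash dilution of
the organic signal, and additive detector noise:

    A(v) = gain * (1 - ash/100) * sum_k (conc_k / 100) * B_k(v)
           + baseline(v) + eps(v)

Two regimes mirror the study conditions: lab *monocultures* with a wide
fatty-acid range (1.32-22.46 %DW, low ash) and wastewater-pond
*polycultures* with uniformly low fatty acids (0.76-4.21 %DW), high protein
(>= 16 %DW) and 10-30 %DW ash that dilutes overall spectral intensity.
Carbohydrate is the remainder-coupled fraction, giving the negative
fatty-acid/carbohydrate correlation expected of storage-compound
partitioning.  Kubelka-Munk diffuse-reflectance nonlinearity, atmospheric
artifacts and instrument line-shape effects are deliberately not modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .spectra import ReferenceTable, SpectraSet, WavenumberGrid


@dataclass(frozen=True)
class BandSpec:
    """One absorbance band: center and FWHM in cm^-1, relative amplitude
    per unit concentration, Gaussian or Lorentzian shape."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        x = (wavenumbers - self.center) / self.fwhm
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-4.0 * np.log(2.0) * x * x)
        return self.amplitude / (1.0 + 4.0 * x * x)


@dataclass(frozen=True)
class ComponentSpectrum:
    """Named biomass component with its band list."""

    name: str
    bands: tuple

    def __post_init__(self) -> None:
        if self.name == "fatty_acid":
            main = max(self.bands, key=lambda b: b.amplitude)
            if main.center != 1740.0:
                raise ValueError(
                    "fatty_acid component must peak at the 1740 cm^-1 ester band"
                )

    def curve(self, wavenumbers: np.ndarray) -> np.ndarray:
        out = np.zeros_like(wavenumbers, dtype=float)
        for b in self.bands:
            out += b.evaluate(wavenumbers)
        return out


def default_component_library() -> list[ComponentSpectrum]:
    """Band library for the four biomass components.

    Fatty acid: strong ester C=O at 1740 with minor CH2/CH3 bending (1470),
    C-O (1160) and CH bending (990) bands.  Protein: Amide I (1650) >
    Amide II (1540), minor 1310.  Carbohydrate: broad C-O-C stretches at
    1030/1080/1150.  Other: one broad low-amplitude background band.

    The absolute amplitude scale sets the noise floor of downstream
    calibrations: with the default additive noise of 0.002 absorbance, a
    pure-component band at amplitude 0.30 yields a fatty-acid-equivalent
    prediction uncertainty of roughly 0.5 %DW, the error magnitude typical
    of KBr-diluted DRIFTS biomass calibrations; peak absorbances of mixed
    samples land in the 0.02-0.2 range.  Components share the same
    *integrated* absorptivity per unit mass (~14 absorbance*cm^-1 per unit
    fraction), so total spectral intensity tracks total organic content and
    mineral-ash dilution rather than the organic composition mix.
    """
    return [
        ComponentSpectrum("fatty_acid", (
            BandSpec(1740.0, 30.0, 0.300),
            BandSpec(1470.0, 25.0, 0.075),
            BandSpec(1160.0, 30.0, 0.060),
            BandSpec(990.0, 25.0, 0.045),
        )),
        ComponentSpectrum("protein", (
            BandSpec(1650.0, 45.0, 0.173),
            BandSpec(1540.0, 40.0, 0.121),
            BandSpec(1310.0, 40.0, 0.035),
        )),
        ComponentSpectrum("carbohydrate", (
            BandSpec(1030.0, 60.0, 0.086),
            BandSpec(1080.0, 60.0, 0.075),
            BandSpec(1150.0, 80.0, 0.054),
        )),
        ComponentSpectrum("other", (
            BandSpec(1200.0, 900.0, 0.016),
        )),
    ]


@dataclass(frozen=True)
class RegimeConfig:
    """Generative parameters for one sample regime.

    Composition fractions are %DW; baseline coefficients are absorbance
    units (offset), per cm^-1 (slope) and per cm^-2 (curvature); gain_sd is
    the log-normal sigma of the multiplicative scatter; noise_sd is additive
    absorbance noise per grid point.
    """

    name: str
    fa_range: tuple = (1.32, 22.46)
    protein_range: tuple = (15.0, 35.0)
    ash_range: tuple = (2.0, 8.0)
    baseline_offset_sd: float = 0.005
    baseline_slope_sd: float = 5e-6
    baseline_curvature_sd: float = 2e-9
    gain_sd: float = 0.1
    noise_sd: float = 0.002
    n: int = 44

    def __post_init__(self) -> None:
        for rng_ in (self.fa_range, self.protein_range, self.ash_range):
            lo, hi = rng_
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError(f"range {rng_} must lie within [0, 100]")
        if self.fa_range[1] + self.protein_range[1] + self.ash_range[1] > 100.0 + 35.0:
            # loose sanity bound; carbohydrate absorbs the remainder
            raise ValueError("component ranges leave no room for carbohydrate")
        if self.gain_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")


def monoculture_regime(n: int = 44, **overrides) -> RegimeConfig:
    """Lab monocultures: wide fatty-acid span, low ash."""
    kw = dict(name="monoculture", fa_range=(1.32, 22.46),
              protein_range=(15.0, 35.0), ash_range=(2.0, 8.0), n=n)
    kw.update(overrides)
    return RegimeConfig(**kw)


def polyculture_regime(n: int = 57, **overrides) -> RegimeConfig:
    """Open-pond polycultures: narrow low fatty-acid span, high protein,
    10-30 %DW ash diluting the organic signal."""
    kw = dict(name="polyculture", fa_range=(0.76, 4.21),
              protein_range=(16.0, 30.0), ash_range=(10.0, 30.0), n=n)
    kw.update(overrides)
    return RegimeConfig(**kw)


MIN_CARBOHYDRATE = 5.0
ORGANIC_TOTAL = 70.0  # fa + protein + carbohydrate pool, %DW


def _compose(regime: RegimeConfig, rng: np.random.Generator) -> dict:
    fa = rng.uniform(*regime.fa_range)
    protein = rng.uniform(*regime.protein_range)
    ash = rng.uniform(*regime.ash_range)
    carb = max(ORGANIC_TOTAL - fa - protein, MIN_CARBOHYDRATE)
    other = max(100.0 - fa - protein - carb - ash, 0.0)
    return {"fa": fa, "protein": protein, "carbohydrate": carb,
            "ash": ash, "other": other}


def simulate_sample(
    regime: RegimeConfig,
    library: list[ComponentSpectrum] | None = None,
    rng: np.random.Generator | None = None,
    grid: WavenumberGrid | None = None,
) -> tuple[np.ndarray, dict]:
    """One raw spectrum on the acquisition grid plus its truth record."""
    if library is None:
        library = default_component_library()
    if rng is None:
        rng = np.random.default_rng()
    if grid is None:
        grid = WavenumberGrid.default()
    wn = grid.values
    comp = _compose(regime, rng)
    conc = {"fatty_acid": comp["fa"], "protein": comp["protein"],
            "carbohydrate": comp["carbohydrate"], "other": comp["other"]}
    signal = np.zeros_like(wn)
    for c in library:
        signal += (conc.get(c.name, 0.0) / 100.0) * c.curve(wn)
    gain = float(np.exp(rng.normal(0.0, regime.gain_sd))) if regime.gain_sd else 1.0
    nu0 = wn.mean()
    baseline = (
        rng.normal(0.0, regime.baseline_offset_sd)
        + rng.normal(0.0, regime.baseline_slope_sd) * (wn - nu0)
        + rng.normal(0.0, regime.baseline_curvature_sd) * (wn - nu0) ** 2
    )
    eps = rng.normal(0.0, regime.noise_sd, wn.size) if regime.noise_sd else 0.0
    spectrum = gain * (1.0 - comp["ash"] / 100.0) * signal + baseline + eps
    truth = {**comp, "gain": gain}
    return spectrum, truth


_SPECIES = ("Chlorella vulgaris", "Scenedesmus obliquus", "Coelastrella sp.",
            "Haematococcus sp.", "Coelastrum sp.")


def _metadata_row(regime: RegimeConfig, rng: np.random.Generator) -> dict:
    if regime.name == "monoculture":
        return {
            "culture_type": "monoculture",
            "species": _SPECIES[rng.integers(len(_SPECIES))],
            "medium": ("BBM", "wastewater")[rng.integers(2)],
            "temperature_C": float((5.0, 22.0)[rng.integers(2)]),
            "duration_days": float(rng.integers(6, 47)),
            "harvest_month": np.nan,
            "year": np.nan,
        }
    return {
        "culture_type": "polyculture",
        "species": None,
        "medium": "wastewater",
        "temperature_C": np.nan,
        "duration_days": np.nan,
        "harvest_month": int(rng.integers(5, 10)),
        "year": int((2017, 2019)[rng.integers(2)]),
    }


def simulate_regime(
    regime: RegimeConfig,
    library: list[ComponentSpectrum] | None = None,
    rng: np.random.Generator | None = None,
    prefix: str = "s",
) -> tuple[SpectraSet, ReferenceTable, pd.DataFrame]:
    """Generate one regime's samples with metadata and truth table."""
    if rng is None:
        rng = np.random.default_rng()
    grid = WavenumberGrid.default()
    width = max(3, len(str(regime.n)))
    ids, rows, meta, truths = [], [], [], []
    for i in range(regime.n):
        spec, truth = simulate_sample(regime, library, rng, grid)
        ids.append(f"{prefix}{i + 1:0{width}d}")
        rows.append(spec)
        meta.append(_metadata_row(regime, rng))
        truths.append(truth)
    metadata = pd.DataFrame(meta, index=ids)
    truth_df = pd.DataFrame(truths, index=ids)
    spectra = SpectraSet(grid, np.vstack(rows), ids, metadata)
    ref = ReferenceTable(pd.Series(truth_df["fa"].to_numpy(), index=ids))
    return spectra, ref, truth_df


def simulate_dataset(
    n_mono: int = 44,
    n_poly: int = 57,
    seed: int = 0,
    library: list[ComponentSpectrum] | None = None,
    mono_overrides: dict | None = None,
    poly_overrides: dict | None = None,
) -> tuple[SpectraSet, ReferenceTable, dict]:
    """Combined two-regime dataset (default n = 44 + 57 = 101).

    Returns (spectra, reference, manifest); the manifest records all regime
    parameters and the seed for full reproducibility.
    """
    if n_mono + n_poly < 8:
        raise ValueError("need at least 8 samples in total")
    rng = np.random.default_rng(seed)
    mono = monoculture_regime(n_mono, **(mono_overrides or {}))
    poly = polyculture_regime(n_poly, **(poly_overrides or {}))
    s_m, r_m, t_m = simulate_regime(mono, library, rng, prefix="mono_")
    s_p, r_p, t_p = simulate_regime(poly, library, rng, prefix="poly_")
    grid = s_m.grid
    spectra = SpectraSet(
        grid,
        np.vstack([s_m.absorbance, s_p.absorbance]),
        s_m.sample_ids + s_p.sample_ids,
        pd.concat([s_m.metadata, s_p.metadata]),
    )
    ref = ReferenceTable(pd.concat([r_m.values, r_p.values]))
    manifest = {
        "seed": int(seed),
        "monoculture": asdict(mono),
        "polyculture": asdict(poly),
        "truth": pd.concat([t_m, t_p]).to_dict(orient="index"),
    }
    return spectra, ref, manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=float)
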