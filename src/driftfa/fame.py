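"""Internal-standard FAME quantification from integrated GC-FID peak areas.

Relative response factors (RRFs) express detector response per unit mass of
each fatty acid methyl ester relative to the C15:0 internal standard (IS):

    RRF_i = (A_i / m_i) / (A_IS / m_IS)

With multi-level calibration the RRF is the least-squares slope through the
origin of (A_i / A_IS) against (m_i / m_IS).  Sample quantification inverts
the same relation,

    m_i = (A_i / A_IS) * m_IS / RRF_i,

and totals are expressed as percent of dry weight of the weighed biomass.
Results are FAME-equivalent masses; no FAME -> free-fatty-acid molecular
weight correction is applied, so users can post-correct if needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INTERNAL_STANDARD = "C15:0"
DEFAULT_IS_MASS_UG = 10.0
DEFAULT_BIOMASS_MG = 20.0


@dataclass(frozen=True)
class RrfTable:
    """Fatty-acid species -> relative response factor (> 0); IS has RRF 1."""

    factors: dict
    internal_standard: str = INTERNAL_STANDARD

    def __post_init__(self) -> None:
        for sp, r in self.factors.items():
            if not np.isfinite(r) or r <= 0:
                raise ValueError(f"RRF for {sp!r} must be finite and > 0")

    def __getitem__(self, species: str) -> float:
        return self.factors[species]


def compute_rrf(cal_areas, cal_masses, is_area, is_mass_ug=DEFAULT_IS_MASS_UG,
                internal_standard: str = INTERNAL_STANDARD) -> RrfTable:
    """RRFs from a calibration mixture, single- or multi-level.

    ``cal_areas``/``cal_masses`` map species -> area(s)/mass(es) in µg;
    scalars give the single-level ratio form, equal-length arrays (with
    matching ``is_area``/``is_mass_ug`` scalars or arrays) give the
    through-origin regression slope of A_i/A_IS vs m_i/m_IS.
    """
    is_area = np.atleast_1d(np.asarray(is_area, dtype=float))
    is_mass = np.atleast_1d(np.asarray(is_mass_ug, dtype=float))
    if (is_area <= 0).any():
        raise ValueError("internal-standard area must be > 0")
    if (is_mass <= 0).any():
        raise ValueError("internal-standard mass must be > 0")
    factors = {internal_standard: 1.0}
    for sp, areas in cal_areas.items():
        a = np.atleast_1d(np.asarray(areas, dtype=float))
        m = np.atleast_1d(np.asarray(cal_masses[sp], dtype=float))
        if (m <= 0).any():
            raise ValueError(f"calibration mass for {sp!r} must be > 0")
        x = m / np.broadcast_to(is_mass, m.shape)
        ycal = a / np.broadcast_to(is_area, a.shape)
        factors[sp] = float((x @ ycal) / (x @ x))  # slope through origin
    return RrfTable(factors, internal_standard)


@dataclass
class PeakAreaTable:
    """Integrated areas of one or more samples plus per-sample context.

    ``areas``: sample_id -> {species -> area}; ``is_area``: sample_id ->
    internal-standard area; ``biomass_mg``: weighed dry biomass per sample.
    """

    areas: dict
    is_area: dict
    biomass_mg: dict
    is_mass_ug: float = DEFAULT_IS_MASS_UG

    def __post_init__(self) -> None:
        for sid, sp_areas in self.areas.items():
            for sp, a in sp_areas.items():
                if a < 0:
                    raise ValueError(f"negative area for {sid!r}/{sp!r}")
            if self.is_area.get(sid, 0.0) <= 0:
                raise ValueError(f"internal-standard area must be > 0 for {sid!r}")
            if self.biomass_mg.get(sid, 0.0) <= 0:
                raise ValueError(f"biomass must be > 0 for {sid!r}")


def quantify_fames(sample_areas: dict, is_area: float, rrf: RrfTable,
                   is_mass_ug: float = DEFAULT_IS_MASS_UG,
                   biomass_mg: float = DEFAULT_BIOMASS_MG) -> dict:
    """Quantify one sample's fatty acids to µg and total %DW.

    Returns {'species_ug': {species: µg}, 'total_fa_pct_dw': float}.
    """
    missing = [sp for sp in sample_areas if sp not in rrf.factors]
    if missing:
        raise KeyError(f"species missing from RRF table: {sorted(missing)}")
    if is_area <= 0:
        raise ValueError("internal-standard area must be > 0")
    if biomass_mg <= 0:
        raise ValueError("biomass must be > 0")
    species_ug = {
        sp: (a / is_area) * is_mass_ug / rrf[sp] for sp, a in sample_areas.items()
    }
    total_ug = sum(species_ug.values())
    return {
        "species_ug": species_ug,
        "total_fa_pct_dw": total_ug / (biomass_mg * 1000.0) * 100.0,
    }


def quantify_table(table: PeakAreaTable, rrf: RrfTable) -> pd.DataFrame:
    """Quantify every sample in a PeakAreaTable.

    Returns a DataFrame indexed by sample_id with a ``total_fa_pct_dw``
    column, directly compatible with a reference table.
    """
    rows = {}
    for sid, sp_areas in table.areas.items():
        res = quantify_fames(
            sp_areas, table.is_area[sid], rrf, table.is_mass_ug,
            table.biomass_mg[sid],
        )
        rows[sid] = res["total_fa_pct_dw"]
    df = pd.DataFrame({"total_fa_pct_dw": pd.Series(rows)})
    df.index.name = "sample_id"
    return df


def read_peak_area_csv(path, is_mass_ug: float = DEFAULT_IS_MASS_UG,
                       internal_standard: str = INTERNAL_STANDARD) -> PeakAreaTable:
    """Long-format CSV: sample_id, species, area, biomass_mg."""
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "species", "area", "biomass_mg"}
    if not required.issubset(df.columns):
        raise ValueError(f"peak-area table needs columns {sorted(required)}")
    areas: dict = {}
    is_area: dict = {}
    biomass: dict = {}
    for sid, sub in df.groupby("sample_id"):
        sid = str(sid)
        biomass[sid] = float(sub["biomass_mg"].iloc[0])
        sp_map = dict(zip(sub["species"].map(str), sub["area"].astype(float)))
        if internal_standard not in sp_map:
            raise ValueError(f"sample {sid!r} lacks internal standard peak")
        is_area[sid] = sp_map.pop(internal_standard)
        areas[sid] = sp_map
    return PeakAreaTable(areas, is_area, biomass, is_mass_ug)


def read_calibration_csv(path) -> tuple[dict, dict]:
    """Calibration-mixture CSV: species, area, mass_ug (multi-level allowed)."""
    df = pd.read_csv(path, comment="#")
    required = {"species", "area", "mass_ug"}
    if not required.issubset(df.columns):
        raise ValueError(f"calibration table needs columns {sorted(required)}")
    areas: dict = {}
    masses: dict = {}
    for sp, sub in df.groupby("species"):
        areas[str(sp)] = sub["area"].to_numpy(dtype=float)
        masses[str(sp)] = sub["mass_ug"].to_numpy(dtype=float)
    return areas, masses
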