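"""Domain containers for infrared spectra and fatty-acid reference data.

Spectra live on a shared wavenumber grid stored strictly *ascending*; the
FTIR convention of plotting wavenumbers descending is presentation-only.
All interchange is plain CSV (UTF-8, "." decimal): a spectral matrix whose
first column (or row) holds wavenumbers in cm^-1, a two-column reference
table of total fatty acid content in percent of dry weight (%DW), and an
optional metadata sidecar keyed by sample id.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METADATA_COLUMNS = (
    "culture_type",
    "species",
    "medium",
    "temperature_C",
    "duration_days",
    "harvest_month",
    "year",
)

CULTURE_TYPES = ("monoculture", "polyculture")


class SpectraError(ValueError):
    """Raised on malformed spectral or reference inputs."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly ascending wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise SpectraError("wavenumber grid needs at least 2 points")
        if not np.all(np.isfinite(v)):
            raise SpectraError("non-finite wavenumber values")
        if not np.all(np.diff(v) > 0):
            raise SpectraError("wavenumber grid must be strictly ascending")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def spacing(self) -> float:
        """Nominal step in cm^-1 (median of successive differences)."""
        return float(np.median(np.diff(self.values)))

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.values)
        return bool(np.allclose(d, d[0], rtol=1e-9, atol=0.0))

    @classmethod
    def default(cls) -> "WavenumberGrid":
        """Full mid-IR acquisition range, 400-4000 cm^-1 at 4 cm^-1 steps."""
        return cls(np.arange(400.0, 4000.0 + 4.0, 4.0))

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.values >= lo) & (self.values <= hi)


@dataclass
class SpectraSet:
    """Absorbance matrix (samples x grid points) with per-sample metadata.

    ``metadata`` is a DataFrame indexed by sample id; missing fields are NaN,
    never sentinel numbers. ``provenance`` accumulates processing records.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    sample_ids: list[str]
    metadata: pd.DataFrame | None = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 2:
            raise SpectraError("absorbance must be a 2-D matrix")
        if a.shape[1] != len(self.grid):
            raise SpectraError(
                f"absorbance width {a.shape[1]} != grid length {len(self.grid)}"
            )
        if a.shape[0] != len(self.sample_ids):
            raise SpectraError("number of sample ids must match matrix rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise SpectraError(f"duplicate sample ids: {dupes}")
        if a.size and not np.all(np.isfinite(a)):
            i, j = np.argwhere(~np.isfinite(a))[0]
            raise SpectraError(
                f"non-finite absorbance at sample {self.sample_ids[i]!r}, "
                f"wavenumber {self.grid.values[j]:g}"
            )
        self.absorbance = a
        self.sample_ids = list(map(str, self.sample_ids))
        if self.metadata is not None:
            self.metadata = self.metadata.reindex(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def select(self, indices: np.ndarray | list[int]) -> "SpectraSet":
        """Row subset preserving grid, metadata and provenance."""
        idx = np.asarray(indices)
        ids = [self.sample_ids[i] for i in idx]
        meta = self.metadata.loc[ids] if self.metadata is not None else None
        return SpectraSet(self.grid, self.absorbance[idx], ids, meta,
                          list(self.provenance))

    def subset_culture(self, culture_type: str) -> "SpectraSet":
        if culture_type not in CULTURE_TYPES:
            raise SpectraError(f"unknown culture type {culture_type!r}")
        if self.metadata is None or "culture_type" not in self.metadata:
            raise SpectraError("no culture_type metadata available")
        mask = (self.metadata["culture_type"] == culture_type).to_numpy()
        return self.select(np.flatnonzero(mask))


@dataclass
class ReferenceTable:
    """Mapping sample id -> total fatty acid content in %DW (>= 0, finite)."""

    values: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.values, dtype=float)
        if s.index.has_duplicates:
            dupes = sorted(s.index[s.index.duplicated()].unique())
            raise SpectraError(f"duplicate sample ids in reference table: {dupes}")
        if len(s) and not np.all(np.isfinite(s.to_numpy())):
            raise SpectraError("non-finite reference values")
        if len(s) and (s.to_numpy() < 0).any():
            bad = s.index[s.to_numpy() < 0][0]
            raise SpectraError(f"negative fatty acid content for sample {bad!r}")
        s.index = s.index.map(str)
        self.values = s

    def __len__(self) -> int:
        return len(self.values)

    def align(self, spectra: SpectraSet) -> np.ndarray:
        """Response vector in the spectra's sample order; unmatched ids raise."""
        if len(self.values) == 0:
            raise SpectraError("empty reference table")
        missing = [s for s in spectra.sample_ids if s not in self.values.index]
        if missing:
            raise SpectraError(f"samples without reference values: {missing}")
        return self.values.loc[spectra.sample_ids].to_numpy()


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

WAVENUMBER_LABEL = "wavenumber_cm1"


def _read_numeric_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", index_col=0)
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise SpectraError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if body.isna().to_numpy().any():
        r, c = np.argwhere(body.isna().to_numpy())[0]
        raise SpectraError(
            f"missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return body


def read_spectra_csv(path, orientation: str = "samples-as-columns",
                     metadata_path=None) -> SpectraSet:
    """Read a spectral matrix from CSV.

    ``samples-as-columns``: first column holds wavenumbers, each remaining
    column is one sample. ``samples-as-rows`` is the transpose (first row
    holds wavenumbers). The grid is coerced to ascending order with the
    absorbance reordered consistently.
    """
    if orientation not in ("samples-as-columns", "samples-as-rows"):
        raise SpectraError(f"unknown orientation {orientation!r}")
    body = _read_numeric_table(path)
    if orientation == "samples-as-rows":
        body = body.T
    wn = body.index.to_numpy(dtype=float)
    if np.unique(wn).size != wn.size:
        raise SpectraError("duplicate wavenumber values")
    order = np.argsort(wn)
    sample_ids = [str(c) for c in body.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise SpectraError("duplicate sample ids in spectra file")
    absorbance = body.to_numpy(dtype=float)[order].T
    grid = WavenumberGrid(wn[order])
    meta = read_metadata_csv(metadata_path) if metadata_path is not None else None
    return SpectraSet(grid, absorbance, sample_ids, meta)


def write_spectra_csv(s: SpectraSet, path) -> None:
    """Write samples-as-columns CSV re-readable by :func:`read_spectra_csv`.

    Values are printed with 12 significant digits, making write/read/write
    byte-idempotent.
    """
    df = pd.DataFrame(
        s.absorbance.T, index=s.grid.values, columns=s.sample_ids
    )
    df.index.name = WAVENUMBER_LABEL
    buf = io.StringIO()
    df.to_csv(buf, float_format="%.12g", lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_metadata_csv(path) -> pd.DataFrame:
    """Metadata sidecar keyed by sample_id; unknown columns pass through."""
    df = pd.read_csv(path, comment="#", index_col="sample_id")
    df.index = df.index.map(str)
    if df.index.has_duplicates:
        raise SpectraError("duplicate sample ids in metadata")
    return df


def write_metadata_csv(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, lineterminator="\n")


def read_reference_table(path) -> ReferenceTable:
    """Two-column CSV: sample_id, total_fa_pct_dw."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        if df.shape[0] == 0:  # header-only or empty file
            return ReferenceTable(pd.Series(dtype=float))
        raise SpectraError("reference table needs columns sample_id,total_fa_pct_dw")
    ids = df.iloc[:, 0].map(str)
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if vals.isna().any():
        bad = ids[vals.isna()].iloc[0]
        raise SpectraError(f"non-numeric fatty acid value for sample {bad!r}")
    return ReferenceTable(pd.Series(vals.to_numpy(), index=ids.to_numpy()))


def write_reference_table(ref: ReferenceTable, path) -> None:
    df = pd.DataFrame(
        {"sample_id": ref.values.index, "total_fa_pct_dw": ref.values.to_numpy()}
    )
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
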