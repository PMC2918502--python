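"""Reflectance-spectrum ingestion and processing.

Raw museum spectra arrive at the instrument's native resolution (~0.4 nm
steps, percent reflectance relative to a white standard).  All downstream
analysis happens on a fixed 5-nm grid spanning 300-700 nm (81 points): each
grid value is the window mean of the piecewise-linear interpolant of the raw
curve over [g-2.5, g+2.5] (edge windows shrink to the intersection with
[300, 700]).  Shape comparisons use *relative* spectra -- each gridded curve
divided by its sum -- and the summed absolute difference between two relative
spectra, a total-variation-style statistic bounded by 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical wavelength grid: 300, 305, ..., 700 nm (81 points).
GRID_NM = np.arange(300.0, 701.0, 5.0)
N_GRID = len(GRID_NM)

#: Columns of the long-format spectra interchange table.
TABLE_COLUMNS = [
    "wavelength_nm",
    "reflectance_pct",
    "family",
    "species",
    "clutch_id",
    "egg_id",
    "replicate_idx",
    "collection_year",
]

KEY_COLUMNS = ["family", "species", "clutch_id", "egg_id", "replicate_idx"]


class SpectraSchemaError(ValueError):
    """A required column is missing or malformed in a spectra table."""


class SpectraValueError(ValueError):
    """Spectral data violate a precondition (coverage, duplicates, ...)."""


@dataclass(frozen=True)
class SampleKey:
    """Hierarchical identity of one replicate measurement of one egg."""

    family: str
    species: str
    clutch_id: str
    egg_id: str
    replicate_idx: int
    collection_year: int | None = None

    def __post_init__(self) -> None:
        for level in ("family", "species", "clutch_id", "egg_id"):
            if not str(getattr(self, level)):
                raise SpectraValueError(f"empty hierarchy key: {level}")
        if not 1 <= int(self.replicate_idx) <= 6:
            raise SpectraValueError(
                f"replicate_idx must be in [1, 6], got {self.replicate_idx}"
            )


@dataclass
class RawSpectrum:
    """Reflectance at native instrument resolution."""

    wavelengths_nm: np.ndarray
    reflectance_pct: np.ndarray
    meta: SampleKey

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.reflectance_pct = np.asarray(self.reflectance_pct, dtype=float)
        if self.wavelengths_nm.shape != self.reflectance_pct.shape:
            raise SpectraValueError("wavelength/reflectance length mismatch")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) < 2:
            raise SpectraValueError("need at least two samples")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise SpectraValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance_pct)):
            raise SpectraValueError("non-finite reflectance values")


@dataclass
class GridSpectrum:
    """Reflectance on the canonical 300-700 nm, 5-nm grid."""

    reflectance_pct: np.ndarray
    meta: SampleKey | None = None
    grid_nm: np.ndarray = field(default_factory=lambda: GRID_NM.copy())

    def __post_init__(self) -> None:
        self.reflectance_pct = np.asarray(self.reflectance_pct, dtype=float)
        if self.reflectance_pct.shape != (N_GRID,):
            raise SpectraValueError(
                f"grid spectrum must have {N_GRID} values, "
                f"got {self.reflectance_pct.shape}"
            )
        if not np.allclose(self.grid_nm, GRID_NM):
            raise SpectraValueError("grid must be the canonical 300:5:700 grid")


@dataclass
class RelativeSpectrum:
    """A grid spectrum normalised to unit sum (shape only)."""

    proportions: np.ndarray
    meta: SampleKey | None = None
    grid_nm: np.ndarray = field(default_factory=lambda: GRID_NM.copy())

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (N_GRID,):
            raise SpectraValueError("relative spectrum must have 81 values")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise SpectraValueError("proportions must sum to 1")
        if np.any(self.proportions < 0):
            raise SpectraValueError("proportions must be nonnegative")


# ---------------------------------------------------------------------------
# I/O


def read_spectra_table(
    path, schema: Mapping[str, str] | None = None
) -> list[RawSpectrum]:
    """Read a long-format spectra CSV into one RawSpectrum per replicate.

    ``schema`` maps canonical column names (see TABLE_COLUMNS) to the file's
    actual column names; by default the canonical names are expected.
    """
    colmap = dict(zip(TABLE_COLUMNS, TABLE_COLUMNS))
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    required = [colmap[c] for c in TABLE_COLUMNS if c != "collection_year"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SpectraSchemaError(f"missing column(s): {', '.join(missing)}")
    for col in ("wavelength_nm", "reflectance_pct"):
        raw = df[colmap[col]]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna()
        if bad.any() or raw.isna().any():
            line = int((vals.isna()).idxmax()) + 2  # header + 0-base
            raise SpectraSchemaError(
                f"non-numeric or missing {col} at line {line}"
            )
        df[colmap[col]] = vals
    yearcol = colmap["collection_year"]
    has_year = yearcol in df.columns

    out: list[RawSpectrum] = []
    keycols = [colmap[c] for c in KEY_COLUMNS]
    for keyvals, grp in df.groupby(keycols, sort=True):
        if grp[colmap["wavelength_nm"]].duplicated().any():
            raise SpectraValueError(
                f"duplicate (key, wavelength) rows for key {keyvals}"
            )
        grp = grp.sort_values(colmap["wavelength_nm"])
        year = None
        if has_year and grp[yearcol].notna().any():
            year = int(grp[yearcol].dropna().iloc[0])
        meta = SampleKey(
            family=str(keyvals[0]),
            species=str(keyvals[1]),
            clutch_id=str(keyvals[2]),
            egg_id=str(keyvals[3]),
            replicate_idx=int(keyvals[4]),
            collection_year=year,
        )
        out.append(
            RawSpectrum(
                wavelengths_nm=grp[colmap["wavelength_nm"]].to_numpy(float),
                reflectance_pct=grp[colmap["reflectance_pct"]].to_numpy(float),
                meta=meta,
            )
        )
    return out


def spectra_to_table(spectra: Iterable[RawSpectrum]) -> pd.DataFrame:
    """Long-format DataFrame in the interchange dialect (inverse of reader)."""
    frames = []
    for s in spectra:
        n = len(s.wavelengths_nm)
        frames.append(
            pd.DataFrame(
                {
                    "wavelength_nm": s.wavelengths_nm,
                    "reflectance_pct": s.reflectance_pct,
                    "family": s.meta.family,
                    "species": s.meta.species,
                    "clutch_id": s.meta.clutch_id,
                    "egg_id": s.meta.egg_id,
                    "replicate_idx": s.meta.replicate_idx,
                    "collection_year": (
                        s.meta.collection_year
                        if s.meta.collection_year is not None
                        else np.nan
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_spectra_table(spectra: Iterable[RawSpectrum], path) -> None:
    # %.17g guarantees float64 values survive a write/read cycle exactly
    spectra_to_table(spectra).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Processing


def _window_means(wl: np.ndarray, refl: np.ndarray) -> np.ndarray:
    """Mean of the piecewise-linear interpolant over each 5-nm grid window.

    Uses the exact cumulative trapezoid integral of the interpolant evaluated
    at the window edges; edge windows are clipped to [300, 700].
    """
    lo = np.maximum(GRID_NM - 2.5, 300.0)
    hi = np.minimum(GRID_NM + 2.5, 700.0)
    # cumulative integral of the piecewise-linear curve at the sample points
    cum = np.concatenate(
        ([0.0], np.cumsum(np.diff(wl) * (refl[:-1] + refl[1:]) / 2.0))
    )

    def cum_at(x: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(wl, x, side="right") - 1, 0, len(wl) - 2)
        x0, x1 = wl[idx], wl[idx + 1]
        y0, y1 = refl[idx], refl[idx + 1]
        dx = x - x0
        # integral within the segment is quadratic in dx
        return cum[idx] + y0 * dx + (y1 - y0) / (x1 - x0) * dx**2 / 2.0

    return (cum_at(hi) - cum_at(lo)) / (hi - lo)


def resample_to_grid(raw: RawSpectrum, *, mode: str = "window_mean") -> GridSpectrum:
    """Truncate to 300-700 nm and average onto the canonical 5-nm grid.

    ``mode='window_mean'`` (default) averages the interpolated curve over each
    [g-2.5, g+2.5] window; ``mode='point'`` simply interpolates at the grid
    points.  Negative raw reflectances (instrument noise) are clipped to zero
    before averaging.
    """
    wl = raw.wavelengths_nm
    if wl[0] > 300.0 + 1e-9 or wl[-1] < 700.0 - 1e-9:
        raise SpectraValueError(
            f"raw spectrum covers [{wl[0]:g}, {wl[-1]:g}] nm; "
            "must cover [300, 700]"
        )
    inside = (wl >= 300.0) & (wl <= 700.0)
    # include the bracketing samples so interpolation at 300/700 is defined
    steps = np.diff(wl[inside])
    if steps.size and steps.max() > 5.0:
        i = int(np.argmax(steps))
        w = wl[inside]
        raise SpectraValueError(
            f"coverage gap of {steps.max():g} nm between "
            f"{w[i]:g} and {w[i + 1]:g} nm"
        )
    refl = np.clip(raw.reflectance_pct, 0.0, None)
    if mode == "window_mean":
        vals = _window_means(wl, refl)
    elif mode == "point":
        vals = np.interp(GRID_NM, wl, refl)
    else:
        raise ValueError(f"unknown resampling mode: {mode!r}")
    return GridSpectrum(reflectance_pct=vals, meta=raw.meta)


def relative_spectrum(s: GridSpectrum) -> RelativeSpectrum:
    """Divide each 5-nm value by the sum of the curve (shape normalisation)."""
    v = np.clip(s.reflectance_pct, 0.0, None)
    total = v.sum()
    if total <= 0:
        raise SpectraValueError("all-zero spectrum has no relative spectrum")
    return RelativeSpectrum(proportions=v / total, meta=s.meta)


def average_spectrum(spectra: Sequence[GridSpectrum]) -> GridSpectrum:
    """Pointwise arithmetic mean of grid spectra (any hierarchy level)."""
    spectra = list(spectra)
    if not spectra:
        raise SpectraValueError("cannot average an empty set of spectra")
    stack = np.stack([s.reflectance_pct for s in spectra])
    meta = spectra[0].meta
    return GridSpectrum(reflectance_pct=stack.mean(axis=0), meta=meta)


def hierarchical_mean(
    spectra: Sequence[GridSpectrum], levels: Sequence[str]
) -> dict[tuple, GridSpectrum]:
    """Nested means: replicates -> egg -> clutch -> species, in one call.

    ``levels`` names the SampleKey fields that define the output grouping
    (e.g. ``("family", "species")`` for species means).  Averaging proceeds
    level by level from the bottom so unbalanced designs are averaged
    hierarchically, not pooled.
    """
    full = ["family", "species", "clutch_id", "egg_id"]
    if list(levels) != full[: len(levels)]:
        raise ValueError(f"levels must be a prefix of {full}")
    groups: dict[tuple, list[GridSpectrum]] = {}
    for s in spectra:
        key = tuple(getattr(s.meta, f) for f in full)
        groups.setdefault(key, []).append(s)
    current = {k: average_spectrum(v) for k, v in groups.items()}
    depth = len(full)
    while depth > len(levels):
        depth -= 1
        nxt: dict[tuple, list[GridSpectrum]] = {}
        for key, spec in current.items():
            nxt.setdefault(key[:depth], []).append(spec)
        current = {k: average_spectrum(v) for k, v in nxt.items()}
    return current


def abs_sum_difference(a: GridSpectrum, b: GridSpectrum) -> float:
    """Summed absolute difference between the two relative spectra.

    Bounded: 0 for identical shapes, 2 for disjoint support.
    """
    ra = relative_spectrum(a).proportions
    rb = relative_spectrum(b).proportions
    return float(np.abs(ra - rb).sum())
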