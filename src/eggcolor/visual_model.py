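"""Tetrachromatic visual modelling for an average UV-sensitive avian eye.

Reflectance spectra are converted to quantum catches of the four single
cones (UVS, SWS, MWS, LWS) plus the double cone, then projected into a
three-dimensional chromatic space in which (i) loci are independent of
stimulus intensity and (ii) Euclidean distance equals the receptor-noise-
limited discriminability Delta-S of the underlying catch vectors, so one
unit is one just-noticeable difference (JND).

Coordinates are fixed by a documented convention: log catches are projected
onto a Helmert-style orthonormal basis of the subspace orthogonal to
(1,1,1,1) whose last contrast opposes the UV cone to the other three, and
that 3-vector is then mapped through the Cholesky factor of the Gram matrix
induced by the receptor-noise metric.  The Z axis is therefore the (noise-
scaled) UV-opponent axis; X and Y mix the longer-wavelength contrasts.  Any
construction with the same distance structure differs from this one only by
a fixed rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import GRID_NM, N_GRID, GridSpectrum

RECEPTOR_ORDER = ("uvs", "sws", "mws", "lws")

#: Default single-cone peak sensitivities (nm) for an average UVS-type eye,
#: plus the double cone used for luminance.
DEFAULT_LAMBDA_MAX = {"uvs": 370.0, "sws": 445.0, "mws": 508.0, "lws": 565.0}
DEFAULT_DOUBLE_LAMBDA_MAX = 565.0


class VisualModelError(ValueError):
    pass


@dataclass
class ReceptorSensitivities:
    """Unit-area sensitivity curves on the canonical grid.

    ``curves`` has shape (5, 81): rows are UVS, SWS, MWS, LWS, double cone.
    Unit area means sum(curve) * 5 nm == 1 for each row.
    """

    curves: np.ndarray
    grid_nm: np.ndarray = field(default_factory=lambda: GRID_NM.copy())

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.shape != (5, N_GRID):
            raise VisualModelError("expected 5 curves of 81 points")
        if np.any(self.curves < 0):
            raise VisualModelError("sensitivities must be nonnegative")

    @property
    def single_cones(self) -> np.ndarray:
        return self.curves[:4]

    @property
    def double_cone(self) -> np.ndarray:
        return self.curves[4]


@dataclass
class Illuminant:
    """Irradiance spectrum; the default is flat (equal energy)."""

    irradiance: np.ndarray = field(
        default_factory=lambda: np.ones(N_GRID)
    )
    grid_nm: np.ndarray = field(default_factory=lambda: GRID_NM.copy())

    def __post_init__(self) -> None:
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        if self.irradiance.shape != (N_GRID,):
            raise VisualModelError("illuminant must have 81 points")
        if np.any(self.irradiance <= 0):
            raise VisualModelError("irradiance must be strictly positive")


@dataclass(frozen=True)
class NoiseModel:
    """Receptor noise: Weber fraction of the LWS cone and relative densities.

    Noise of receptor i is e_i = weber_lws * sqrt(density_lws / density_i);
    the conventional defaults are weber 0.05 and densities (1, 2, 2, 4) for
    (UVS, SWS, MWS, LWS).
    """

    weber_lws: float = 0.05
    relative_densities: tuple[float, float, float, float] = (1.0, 2.0, 2.0, 4.0)

    def __post_init__(self) -> None:
        if self.weber_lws <= 0 or any(d <= 0 for d in self.relative_densities):
            raise VisualModelError("noise parameters must be positive")

    @property
    def noise(self) -> np.ndarray:
        d = np.asarray(self.relative_densities, dtype=float)
        return self.weber_lws * np.sqrt(d[3] / d)


@dataclass(frozen=True)
class QuantumCatches:
    uvs: float
    sws: float
    mws: float
    lws: float
    double: float

    @property
    def singles(self) -> np.ndarray:
        return np.array([self.uvs, self.sws, self.mws, self.lws])


@dataclass(frozen=True)
class ChromaticLocus:
    """Point in the JND-scaled chromatic space (intensity factored out)."""

    X: float
    Y: float
    Z: float
    luminance_catch: float = 1.0

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z])


# ---------------------------------------------------------------------------
# Sensitivities


def _nomogram(lambda_max: float, width: float = 0.05) -> np.ndarray:
    """Log-normal visual-pigment absorbance template (alpha band only).

    A smooth unimodal curve peaked at lambda_max; ``width`` is the SD of the
    Gaussian in ln(wavelength).  This is a pigment-only template: no ocular
    media or oil-droplet filtering.
    """
    return np.exp(-0.5 * (np.log(GRID_NM / lambda_max) / width) ** 2)


def build_sensitivities(
    mode: str = "template",
    *,
    lambda_max: dict | None = None,
    double_lambda_max: float | None = None,
    path=None,
    width: float = 0.05,
) -> ReceptorSensitivities:
    """Receptor sensitivity curves, from a nomogram template or a CSV table.

    Template mode parameterises each cone only by its peak wavelength.
    Table mode reads columns wavelength_nm, uvs, sws, mws, lws[, double]
    covering at least 300-700 nm (any published sensitivity set, including
    ones with oil-droplet filtering, can be supplied this way).
    """
    if mode == "template":
        lmax = dict(DEFAULT_LAMBDA_MAX)
        if lambda_max:
            lmax.update(lambda_max)
        dbl = double_lambda_max or DEFAULT_DOUBLE_LAMBDA_MAX
        for name, lm in {**lmax, "double": dbl}.items():
            if not 300.0 < lm < 700.0:
                raise VisualModelError(
                    f"lambda_max for {name} must lie in (300, 700), got {lm}"
                )
        curves = np.stack(
            [_nomogram(lmax[r], width) for r in RECEPTOR_ORDER]
            + [_nomogram(dbl, width)]
        )
    elif mode == "table":
        df = pd.read_csv(path)
        if "wavelength_nm" not in df.columns:
            raise VisualModelError("table needs a wavelength_nm column")
        wl = df["wavelength_nm"].to_numpy(float)
        if not np.all(np.diff(wl) > 0):
            raise VisualModelError("wavelength column must be increasing")
        if wl[0] > 300.0 or wl[-1] < 700.0:
            raise VisualModelError("table must cover 300-700 nm")
        cols = list(RECEPTOR_ORDER) + (
            ["double"] if "double" in df.columns else ["lws"]
        )
        missing = [c for c in RECEPTOR_ORDER if c not in df.columns]
        if missing:
            raise VisualModelError(f"table missing columns: {missing}")
        curves = np.stack(
            [np.interp(GRID_NM, wl, df[c].to_numpy(float)) for c in cols]
        )
    else:
        raise VisualModelError(f"unknown mode: {mode!r}")
    # unit area on the grid: sum * 5 nm = 1
    areas = curves.sum(axis=1) * 5.0
    if np.any(areas <= 0):
        raise VisualModelError("each sensitivity curve must have positive area")
    return ReceptorSensitivities(curves=curves / areas[:, None])


def write_sensitivity_table(sens: ReceptorSensitivities, path) -> None:
    df = pd.DataFrame({"wavelength_nm": GRID_NM})
    for i, name in enumerate(RECEPTOR_ORDER):
        df[name] = sens.curves[i]
    df["double"] = sens.curves[4]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Catches and loci


def quantum_catches(
    s: GridSpectrum,
    sens: ReceptorSensitivities,
    ill: Illuminant | None = None,
) -> QuantumCatches:
    """q_i = sum_k sens_i(l_k) * R(l_k) * I(l_k) over the 81 grid points."""
    ill = ill or Illuminant()
    stim = np.clip(s.reflectance_pct, 0.0, None) * ill.irradiance
    q = sens.curves @ stim
    if np.any(q[:4] <= 0) or q[4] <= 0:
        raise VisualModelError(
            "zero quantum catch in at least one receptor (log undefined)"
        )
    return QuantumCatches(*map(float, q))


def _helmert_basis() -> np.ndarray:
    """Orthonormal basis of the subspace of R^4 orthogonal to (1,1,1,1).

    Row order fixes the axis convention: MWS-LWS contrast, SWS vs (MWS+LWS),
    and last the UV-opponent contrast (-> Z axis).
    """
    H = np.array(
        [
            [0.0, 0.0, 1.0, -1.0],
            [0.0, 2.0, -1.0, -1.0],
            [3.0, -1.0, -1.0, -1.0],
        ]
    )
    return H / np.linalg.norm(H, axis=1, keepdims=True)


def _rnl_metric(noise: NoiseModel) -> np.ndarray:
    """4x4 PSD matrix M with Delta-S^2 = df' M df (rank 3, null space = 1)."""
    e = noise.noise
    idx = range(4)
    denom = sum(
        (e[i] * e[j] * e[k]) ** 2 for i, j, k in combinations(idx, 3)
    )
    M = np.zeros((4, 4))
    for i, j in combinations(idx, 2):
        others = [k for k in idx if k not in (i, j)]
        w = (e[others[0]] * e[others[1]]) ** 2
        u = np.zeros(4)
        u[i], u[j] = 1.0, -1.0
        M += w * np.outer(u, u)
    return M / denom


def _locus_transform(noise: NoiseModel) -> np.ndarray:
    """3x4 matrix A with |A(fa - fb)| = Delta-S(fa, fb); rows give (X, Y, Z).

    A = L' H where H is the Helmert basis and L L' = H M H' (Cholesky);
    lower-triangularity of L makes Z a pure noise-scaled UV contrast.
    """
    H = _helmert_basis()
    G = H @ _rnl_metric(noise) @ H.T
    L = np.linalg.cholesky(G)
    return L.T @ H


def chromatic_locus(
    q: QuantumCatches | Sequence[float], noise: NoiseModel | None = None
) -> ChromaticLocus:
    """Map catches to (X, Y, Z); equal catches map to the origin and scaling
    the stimulus leaves the locus unchanged."""
    noise = noise or NoiseModel()
    if isinstance(q, QuantumCatches):
        singles, dbl = q.singles, q.double
    else:
        singles, dbl = np.asarray(q, dtype=float), 1.0
    if np.any(singles <= 0):
        raise VisualModelError("quantum catches must be positive")
    coords = _locus_transform(noise) @ np.log(singles)
    return ChromaticLocus(
        X=float(coords[0]),
        Y=float(coords[1]),
        Z=float(coords[2]),
        luminance_catch=float(dbl),
    )


def delta_e(a: ChromaticLocus, b: ChromaticLocus) -> float:
    """Euclidean distance in (X, Y, Z): perceptual distance in JND units."""
    return float(np.linalg.norm(a.xyz - b.xyz))


def rnl_discriminability(
    qa: Sequence[float], qb: Sequence[float], noise: NoiseModel | None = None
) -> float:
    """Closed-form tetrachromatic receptor-noise Delta-S between two catch
    vectors (the quantity delta_e reproduces as a coordinate distance)."""
    noise = noise or NoiseModel()
    df = np.log(np.asarray(qa, float)) - np.log(np.asarray(qb, float))
    return float(np.sqrt(df @ _rnl_metric(noise) @ df))


def jnd_summary(
    species_loci: dict[str, Sequence[ChromaticLocus]],
    radius: float = 1.0,
) -> tuple[ChromaticLocus, float]:
    """Median locus and the fraction of species within ``radius`` JND of it.

    The median is the coordinate-wise median of the species-average loci;
    the fraction counts species with at least one *individual* locus within
    the radius.
    """
    if not species_loci:
        raise VisualModelError("empty species set")
    means = np.stack(
        [
            np.mean([l.xyz for l in loci], axis=0)
            for loci in species_loci.values()
        ]
    )
    med = np.median(means, axis=0)
    median_locus = ChromaticLocus(X=med[0], Y=med[1], Z=med[2])
    n_within = sum(
        any(np.linalg.norm(l.xyz - med) <= radius for l in loci)
        for loci in species_loci.values()
    )
    return median_locus, n_within / len(species_loci)


def loci_to_frame(loci: dict[str, ChromaticLocus]) -> pd.DataFrame:
    """Species loci as a CSV-ready table (species, X, Y, Z, luminance)."""
    return pd.DataFrame(
        {
            "species": list(loci),
            "X": [l.X for l in loci.values()],
            "Y": [l.Y for l in loci.values()],
            "Z": [l.Z for l in loci.values()],
            "luminance_catch": [l.luminance_catch for l in loci.values()],
        }
    )
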