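"""Scalar and profile colour statistics computed directly from spectra.

Luminance is the achromatic signal proxy for the avian double cone: the sum
of gridded reflectance over 500-700 nm.  Brightness is the total area term,
the sum over the full 300-700 nm grid.  Replicate consistency within an egg
is summarised by a per-wavelength signal-to-noise profile (mean / sample SD
over the six replicate spectra).  Spectra are classified by the receptor
region (UV/SWS/MWS/LWS) containing their global reflectance maximum, and
pairwise shape differences are localised by the wavelength of the largest
relative-spectrum difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra import GRID_NM, GridSpectrum, SpectraValueError, relative_spectrum

LUMINANCE_BAND = (500.0, 700.0)
_LUM_MASK = (GRID_NM >= LUMINANCE_BAND[0]) & (GRID_NM <= LUMINANCE_BAND[1])


@dataclass(frozen=True)
class RegionBoundaries:
    """Contiguous receptor-region intervals partitioning [300, 700] nm.

    Each field is (low, high); a wavelength w belongs to the first region
    with low <= w < high, except the last region which includes its upper
    endpoint.  Defaults are a documented approximation: UV [300,400),
    SWS [400,475), MWS [475,575), LWS [575,700].
    """

    uv: tuple[float, float] = (300.0, 400.0)
    sws: tuple[float, float] = (400.0, 475.0)
    mws: tuple[float, float] = (475.0, 575.0)
    lws: tuple[float, float] = (575.0, 700.0)

    def __post_init__(self) -> None:
        ivals = [self.uv, self.sws, self.mws, self.lws]
        if ivals[0][0] != 300.0 or ivals[-1][1] != 700.0:
            raise ValueError("regions must cover [300, 700]")
        for (a, b), (c, _) in zip(ivals, ivals[1:]):
            if b != c:
                raise ValueError("regions must be contiguous")
        if any(a >= b for a, b in ivals):
            raise ValueError("regions must be non-degenerate")

    def label_of(self, wavelength: float) -> str:
        for name, (a, b) in zip(
            ("UV", "SWS", "MWS", "LWS"),
            (self.uv, self.sws, self.mws, self.lws),
        ):
            if a <= wavelength < b:
                return name
        if wavelength == self.lws[1]:
            return "LWS"
        raise ValueError(f"wavelength {wavelength} outside [300, 700]")


@dataclass
class SnrProfile:
    """Per-wavelength mean, SD and SNR among replicate spectra of one egg."""

    grid_nm: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    snr: np.ndarray
    undefined_mask: np.ndarray  # True where sd == 0 (SNR undefined)


def luminance(s: GridSpectrum) -> float:
    """Sum of reflectance at the 41 grid points in 500-700 nm inclusive."""
    return float(s.reflectance_pct[_LUM_MASK].sum())


def brightness(s: GridSpectrum) -> float:
    """Sum of reflectance over all 81 grid points (total area term)."""
    return float(s.reflectance_pct.sum())


def snr_profile(replicates: Sequence[GridSpectrum]) -> SnrProfile:
    """Signal-to-noise (mean / sample SD) profile among replicates of an egg."""
    replicates = list(replicates)
    if len(replicates) < 2:
        raise SpectraValueError("snr_profile needs at least 2 replicates")
    eggs = {
        (r.meta.family, r.meta.species, r.meta.clutch_id, r.meta.egg_id)
        for r in replicates
        if r.meta is not None
    }
    if len(eggs) > 1:
        raise SpectraValueError(
            f"replicates span multiple eggs: {sorted(eggs)}"
        )
    stack = np.stack([r.reflectance_pct for r in replicates])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    # identical replicates must mask as undefined even when accumulated
    # rounding leaves an SD of a few ulp
    undefined = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    snr = np.full_like(mean, np.nan)
    np.divide(mean, sd, out=snr, where=~undefined)
    return SnrProfile(
        grid_nm=GRID_NM.copy(),
        mean=mean,
        sd=sd,
        snr=snr,
        undefined_mask=undefined,
    )


def classify_max_region(
    s: GridSpectrum, boundaries: RegionBoundaries | None = None
) -> str:
    """Region (UV/SWS/MWS/LWS) containing the spectrum's global maximum.

    Ties are broken toward the longest wavelength, so a constant spectrum
    classifies as LWS.
    """
    b = boundaries or RegionBoundaries()
    v = s.reflectance_pct
    best = np.flatnonzero(v == v.max())[-1]
    return b.label_of(float(GRID_NM[best]))


def max_difference_wavelength(
    a: GridSpectrum, b: GridSpectrum
) -> tuple[float, float, bool]:
    """Wavelength of the largest |relative(a) - relative(b)| difference.

    Returns (wavelength_nm, difference, zero_flag); ties break to the
    shortest wavelength.  Identical shapes return (300.0, 0.0, True).
    """
    d = np.abs(
        relative_spectrum(a).proportions - relative_spectrum(b).proportions
    )
    idx = int(np.argmax(d))  # argmax takes the first (shortest-wavelength) tie
    diff = float(d[idx])
    if diff <= 1e-12:  # identical shapes up to rounding
        return 300.0, 0.0, True
    return float(GRID_NM[idx]), diff, False


def fraction_max_diff_in_interval(
    pairs: Sequence[tuple[GridSpectrum, GridSpectrum]],
    low: float,
    high: float,
) -> float:
    """Fraction of pairs whose largest relative difference falls in [low, high]."""
    if not pairs:
        raise SpectraValueError("no pairs supplied")
    hits = 0
    for a, b in pairs:
        wl, _, zero = max_difference_wavelength(a, b)
        if not zero and low <= wl <= high:
            hits += 1
    return hits / len(pairs)
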