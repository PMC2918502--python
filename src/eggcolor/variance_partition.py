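"""Moment-based nested ANOVA variance components at five taxonomic levels.

Observations are keyed (family, species, clutch, egg, replicate).  The
hierarchical (Type I) analysis computes, level by level, sums of squares
from nested group means, the expected-mean-square (EMS) coefficients
appropriate to the possibly unbalanced design, and solves the resulting
triangular system bottom-up for the variance components.  Negative moment
estimates are reported raw and truncated to zero before percentages are
formed, so percentage profiles are interpretable as cumulative stacks.

For a grid of spectra the same decomposition is applied independently at
each of the 81 wavelengths (``variance_profile``); for scalar colour traits
(luminance, X, Y, Z) it is applied to the per-replicate trait values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import GRID_NM, GridSpectrum

LEVELS = ("family", "species", "clutch", "egg", "replicate")
_KEY_FIELDS = ("family", "species", "clutch_id", "egg_id")


class DesignError(ValueError):
    pass


@dataclass
class NestedDesign:
    """Grouping structure of a five-level nested design, value-agnostic.

    ``codes`` maps each non-error level to an integer group id per
    observation, where groups at a level are nested paths (a clutch id is
    unique to its species, etc.).  The same design can be reused to analyse
    many response vectors (e.g. all 81 wavelengths) cheaply.
    """

    codes: dict[str, np.ndarray]
    n_obs: int

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NestedDesign":
        """Build from a table with family/species/clutch_id/egg_id columns."""
        missing = [c for c in _KEY_FIELDS if c not in df.columns]
        if missing:
            raise DesignError(f"missing design columns: {missing}")
        codes: dict[str, np.ndarray] = {}
        for depth, level in enumerate(LEVELS[:4], start=1):
            path = list(zip(*(df[c].astype(str) for c in _KEY_FIELDS[:depth])))
            codes[level] = pd.factorize(pd.Series(path))[0]
        n_groups = {lvl: codes[lvl].max() + 1 for lvl in codes}
        if n_groups["family"] < 2:
            raise DesignError("need >= 2 families at the top level")
        prev = 1
        for lvl in LEVELS[:4]:
            if n_groups[lvl] == prev:
                # no level anywhere splits into subgroups -> no replication
                raise DesignError(f"no replication at level: {lvl}")
            prev = n_groups[lvl]
        if len(df) == n_groups["egg"]:
            raise DesignError("no replication at level: replicate")
        return cls(codes=codes, n_obs=len(df))


@dataclass
class VarianceComponentsResult:
    """Components, percentages and the underlying ANOVA table per level.

    Arrays are ordered (family, species, clutch, egg, replicate).  Raw
    components may be negative; ``components`` are truncated at zero and
    ``percentages`` sum to 100 unless the data are constant (``degenerate``).
    """

    components: np.ndarray
    raw_components: np.ndarray
    percentages: np.ndarray
    sums_of_squares: np.ndarray
    dfs: np.ndarray
    mean_squares: np.ndarray
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(zip(LEVELS, self.percentages))


def _group_stats(code: np.ndarray, y: np.ndarray):
    """Per-group totals and sizes for one nesting level."""
    n = np.bincount(code)
    t = np.bincount(code, weights=y)
    return t, n


def nested_variance_components(
    design: NestedDesign | pd.DataFrame,
    values: np.ndarray | None = None,
) -> VarianceComponentsResult:
    """Five-level nested ANOVA variance components.

    Accepts either a prebuilt NestedDesign plus a response vector, or a
    DataFrame with the design columns and a ``value`` column.
    """
    if isinstance(design, pd.DataFrame):
        if values is None:
            if "value" not in design.columns:
                raise DesignError("DataFrame input needs a 'value' column")
            values = design["value"].to_numpy(float)
        design = NestedDesign.from_frame(design)
    y = np.asarray(values, dtype=float)
    if y.shape != (design.n_obs,):
        raise DesignError("response length does not match design")

    N = design.n_obs
    grand = y.sum()
    # uncorrected sums of squares of group means, outermost to innermost
    uss = [grand**2 / N]
    k_groups = [1]
    sizes: list[np.ndarray] = [np.array([N])]
    for level in LEVELS[:4]:
        t, n = _group_stats(design.codes[level], y)
        uss.append(float((t**2 / n).sum()))
        k_groups.append(len(n))
        sizes.append(n)
    uss.append(float((y**2).sum()))
    k_groups.append(N)

    ss = np.diff(uss)  # SS for family, species, clutch, egg, replicate(error)
    dfs = np.diff(k_groups).astype(float)
    if np.any(dfs <= 0):
        lvl = LEVELS[int(np.flatnonzero(dfs <= 0)[0])]
        raise DesignError(f"no degrees of freedom at level: {lvl}")
    ms = ss / dfs

    # EMS coefficients: coefficient of component s (s >= r, nested deeper
    # ordering family=0 .. egg=3) in the expected mean square of level r is
    #   [ sum_{g at r} (sum_{h at s within g} n_h^2) / n_g
    #     - sum_{g at r-1} (same) / n_g ] / df_r
    # computed from group sizes alone; the error (replicate) coefficient is 1.
    codes = [np.zeros(N, dtype=int)] + [design.codes[l] for l in LEVELS[:4]]
    coef = np.zeros((5, 5))
    coef[:, 4] = 1.0  # replicate component appears in every EMS
    for s in range(1, 5):  # component index: 1=family .. 4=egg in `codes`
        n_s = sizes[s]
        for r in range(1, s + 1):
            # sum over r-level groups of (sum of squared s-level sizes)/n_g
            inner = np.bincount(codes[r], weights=n_s[codes[s]])
            # inner[g] = sum over obs in g of n_{s-group(obs)} = sum_h n_h^2
            upper = float((inner / sizes[r]).sum())
            inner_prev = np.bincount(codes[r - 1], weights=n_s[codes[s]])
            lower = float((inner_prev / sizes[r - 1]).sum())
            coef[r - 1, s - 1] = (upper - lower) / dfs[r - 1]

    raw = np.zeros(5)
    raw[4] = ms[4]
    for r in range(3, -1, -1):
        raw[r] = (ms[r] - raw[4] - coef[r, r + 1 : 4] @ raw[r + 1 : 4]) / coef[
            r, r
        ]
    components = np.clip(raw, 0.0, None)
    total = components.sum()
    if total <= 0:
        return VarianceComponentsResult(
            components=components,
            raw_components=raw,
            percentages=np.zeros(5),
            sums_of_squares=ss,
            dfs=dfs,
            mean_squares=ms,
            degenerate=True,
        )
    return VarianceComponentsResult(
        components=components,
        raw_components=raw,
        percentages=components / total * 100.0,
        sums_of_squares=ss,
        dfs=dfs,
        mean_squares=ms,
    )


@dataclass
class VarianceProfile:
    """Per-wavelength variance-component percentages (81-point profile)."""

    grid_nm: np.ndarray
    results: list[VarianceComponentsResult]

    @property
    def percentages(self) -> np.ndarray:
        """(81, 5) array ordered (family, species, clutch, egg, replicate)."""
        return np.stack([r.percentages for r in self.results])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wavelength_nm": self.grid_nm})
        pct = self.percentages
        raw = np.stack([r.raw_components for r in self.results])
        for i, level in enumerate(LEVELS):
            df[f"component_{level}"] = raw[:, i]
            df[f"pct_{level}"] = pct[:, i]
        return df


def variance_profile(spectra: list[GridSpectrum]) -> VarianceProfile:
    """Nested variance components independently at each grid wavelength."""
    meta = pd.DataFrame(
        {
            "family": [s.meta.family for s in spectra],
            "species": [s.meta.species for s in spectra],
            "clutch_id": [s.meta.clutch_id for s in spectra],
            "egg_id": [s.meta.egg_id for s in spectra],
        }
    )
    design = NestedDesign.from_frame(meta)
    stack = np.stack([s.reflectance_pct for s in spectra])
    results = [
        nested_variance_components(design, stack[:, k])
        for k in range(stack.shape[1])
    ]
    return VarianceProfile(grid_nm=GRID_NM.copy(), results=results)


def scalar_partition(
    meta: pd.DataFrame, traits: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Variance-component percentages for several scalar traits at once.

    ``meta`` holds the design columns (one row per replicate observation);
    ``traits`` maps trait name to its per-observation values.  Returns a
    tidy table (trait x level percentages).
    """
    design = NestedDesign.from_frame(meta)
    rows = []
    for name, vals in traits.items():
        res = nested_variance_components(design, np.asarray(vals, float))
        row = {"trait": name}
        row.update({f"pct_{l}": p for l, p in zip(LEVELS, res.percentages)})
        rows.append(row)
    return pd.DataFrame(rows)
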