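"""Taxonomic sister-pair comparisons and the auxiliary inferential tests.

Sister pairs are independent pairs of species (each species used at most
once) matched at the shallowest taxonomic rank that admits a partner:
within genus first, then tribe, subfamily, family, and finally across
families.  Spectral-shape differences across those distance categories are
compared by one-way ANOVA.  Museum-storage effects are tested by a paired
t-test of clutch luminance and by linear (Gaussian-identity) regressions of
the luminance and spectral-shape deltas on log time-between-collections.
A randomization test checks whether a focal species sample is biased with
respect to a trait, and maculation scoring is summarised by between-observer
repeatability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

RANKS = ("genus", "tribe", "subfamily", "family")
PAIR_LEVELS = ("congeneric", "tribe", "subfamily", "family", "between-family")


class ComparativeError(ValueError):
    pass


@dataclass
class TaxonomyTable:
    """Species -> (genus, tribe, subfamily, family), with nesting checked."""

    table: pd.DataFrame  # index: species; columns: genus..family

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaxonomyTable":
        need = ["species", *RANKS]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ComparativeError(f"taxonomy missing columns: {missing}")
        t = df.set_index("species")[list(RANKS)].astype(str)
        if t.index.duplicated().any():
            raise ComparativeError("duplicate species in taxonomy")
        # consistency: same genus => same tribe => same subfamily => same family
        for lower, upper in zip(RANKS, RANKS[1:]):
            if (t.groupby(lower)[upper].nunique() > 1).any():
                raise ComparativeError(
                    f"rank nesting violated: one {lower} maps to several {upper}"
                )
        return cls(table=t)

    @property
    def species(self) -> list[str]:
        return sorted(self.table.index)


@dataclass(frozen=True)
class SisterPair:
    species_a: str
    species_b: str
    level: str  # one of PAIR_LEVELS
    spectral_difference: float | None = None


@dataclass(frozen=True)
class StoragePair:
    species: str
    year_old: int
    year_new: int
    delta_luminance: float
    delta_spectral: float

    @property
    def delta_years(self) -> int:
        return self.year_new - self.year_old


def extract_sister_pairs(
    tax: TaxonomyTable,
    differences: dict[frozenset, float] | None = None,
) -> tuple[list[SisterPair], list[str]]:
    """Greedy shallowest-first independent pairing of species.

    Species are paired within genera first; leftovers are paired within
    tribes, then subfamilies, then families, then across families.  Ties are
    broken by sorted species label so the pairing is deterministic.  Returns
    the pairs and any single leftover species (at most one).
    """
    if len(tax.species) < 2:
        raise ComparativeError("need at least 2 species to pair")
    unpaired = list(tax.species)  # sorted
    pairs: list[SisterPair] = []

    def take_pairs(groups: dict, level: str) -> None:
        for key in sorted(groups):
            members = groups[key]
            while len(members) >= 2:
                a, b = members.pop(0), members.pop(0)
                unpaired.remove(a)
                unpaired.remove(b)
                diff = None
                if differences is not None:
                    diff = differences.get(frozenset((a, b)))
                pairs.append(SisterPair(a, b, level, diff))

    for rank, level in zip(RANKS, PAIR_LEVELS[:4]):
        groups: dict[str, list[str]] = {}
        for sp in unpaired:
            groups.setdefault(tax.table.at[sp, rank], []).append(sp)
        take_pairs(groups, level)
    take_pairs({"": list(unpaired)}, "between-family")
    return pairs, unpaired


@dataclass
class PairAnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    level_summary: pd.DataFrame  # median/quartiles/n per level
    dropped_levels: list[str]


def sister_pair_anova(pairs: list[SisterPair]) -> PairAnovaResult:
    """One-way ANOVA of spectral difference across taxonomic-distance levels."""
    by_level: dict[str, list[float]] = {}
    for p in pairs:
        if p.spectral_difference is None:
            raise ComparativeError(
                f"pair ({p.species_a}, {p.species_b}) has no spectral difference"
            )
        by_level.setdefault(p.level, []).append(p.spectral_difference)
    dropped = [lvl for lvl, v in by_level.items() if len(v) < 2]
    kept = {lvl: v for lvl, v in by_level.items() if len(v) >= 2}
    if len(kept) < 2:
        raise ComparativeError("need >= 2 levels with >= 2 pairs each")
    groups = [np.asarray(kept[lvl], float) for lvl in sorted(kept)]
    n_total = sum(len(g) for g in groups)
    k = len(groups)
    allvals = np.concatenate(groups)
    if np.ptp(allvals) == 0.0:  # constant data: no variance at either stratum
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*groups)
    summary = pd.DataFrame(
        [
            {
                "level": lvl,
                "n": len(v),
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)),
            }
            for lvl, v in sorted(kept.items())
        ]
    )
    return PairAnovaResult(
        F=float(F),
        df_between=k - 1,
        df_within=n_total - k,
        p=float(p),
        level_summary=summary,
        dropped_levels=dropped,
    )


@dataclass
class RegressionFit:
    estimate: float
    std_err: float
    t: float
    p: float
    intercept: float
    n: int


@dataclass
class StorageTestResult:
    paired_t: float
    paired_p: float
    n: int
    luminance_on_log_years: RegressionFit
    spectral_on_log_years: RegressionFit
    n_excluded: int


def _ols_on_log_years(y: np.ndarray, log_dy: np.ndarray) -> RegressionFit:
    X = sm.add_constant(log_dy)
    fit = sm.OLS(y, X).fit()
    return RegressionFit(
        estimate=float(fit.params[1]),
        std_err=float(fit.bse[1]),
        t=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
        n=len(y),
    )


def storage_effect_tests(pairs: list[StoragePair]) -> StorageTestResult:
    """Museum-storage effects from the oldest/newest clutch pair per species.

    (a) Paired t-test of newer- vs older-clutch luminance (via the per-pair
    delta); (b) OLS of the luminance delta and of the spectral-shape delta on
    the natural log of the years between collections.
    """
    usable = [p for p in pairs if p.delta_years > 0]
    n_excluded = len(pairs) - len(usable)
    if len(usable) < 3:
        raise ComparativeError("need >= 3 storage pairs with delta_years > 0")
    d_lum = np.array([p.delta_luminance for p in usable])
    d_spec = np.array([p.delta_spectral for p in usable])
    log_dy = np.log([p.delta_years for p in usable])
    if np.allclose(d_lum, 0.0):
        t_stat, t_p = 0.0, 1.0
    else:
        t_stat, t_p = stats.ttest_1samp(d_lum, 0.0)
    return StorageTestResult(
        paired_t=float(t_stat),
        paired_p=float(t_p),
        n=len(usable),
        luminance_on_log_years=_ols_on_log_years(d_lum, log_dy),
        spectral_on_log_years=_ols_on_log_years(d_spec, log_dy),
        n_excluded=n_excluded,
    )


@dataclass
class RandomizationResult:
    observed_median: float
    envelope_low: float
    envelope_high: float
    inside: bool
    n_draw: int
    reps: int


def sampling_randomization(
    pool: np.ndarray,
    focal: np.ndarray,
    n_draw: int | None = None,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> RandomizationResult:
    """Is the focal sample's median typical of random draws from the pool?

    Draws ``n_draw`` values from ``pool`` without replacement ``reps`` times
    and compares the observed focal median with the empirical 2.5-97.5
    percentile envelope of the randomized medians.
    """
    pool = np.asarray(pool, float)
    focal = np.asarray(focal, float)
    if n_draw is None:
        n_draw = len(focal)
    if n_draw > len(pool):
        raise ComparativeError("n_draw exceeds pool size")
    if reps < 100:
        raise ComparativeError("need at least 100 randomization replicates")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    medians = np.array(
        [np.median(rng.choice(pool, size=n_draw, replace=False)) for _ in range(reps)]
    )
    lo, hi = np.percentile(medians, [2.5, 97.5])
    obs = float(np.median(focal))
    return RandomizationResult(
        observed_median=obs,
        envelope_low=float(lo),
        envelope_high=float(hi),
        inside=bool(lo <= obs <= hi),
        n_draw=n_draw,
        reps=reps,
    )


@dataclass
class RepeatabilityResult:
    species_scores: pd.Series  # mean over eggs and observers, per species
    observer_correlation: float
    n_species: int


def maculation_repeatability(scores: pd.DataFrame) -> RepeatabilityResult:
    """Two-observer 3-point maculation scoring summary.

    ``scores`` needs columns species, egg_id, observer_a, observer_b with
    per-egg scores in {0, 1, 2}.  Returns per-species average scores and the
    Pearson correlation of the two observers' per-species means.
    """
    need = ["species", "egg_id", "observer_a", "observer_b"]
    missing = [c for c in need if c not in scores.columns]
    if missing:
        raise ComparativeError(f"scores missing columns: {missing}")
    for col in ("observer_a", "observer_b"):
        if not scores[col].isin([0, 1, 2]).all():
            bad = scores.loc[~scores[col].isin([0, 1, 2]), col].iloc[0]
            raise ComparativeError(f"score outside {{0,1,2}} in {col}: {bad}")
    per_species = scores.groupby("species")[["observer_a", "observer_b"]].mean()
    if len(per_species) < 2:
        raise ComparativeError("need >= 2 species for repeatability")
    r = float(
        np.corrcoef(per_species["observer_a"], per_species["observer_b"])[0, 1]
    )
    return RepeatabilityResult(
        species_scores=per_species.mean(axis=1),
        observer_correlation=r,
        n_species=len(per_species),
    )
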