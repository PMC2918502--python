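"""End-to-end analysis pipeline over a spectra dataset.

Mirrors the study workflow: ingest (or generate) raw spectra -> canonical
grid -> colour statistics and tetrachromatic loci -> JND summary ->
variance partitioning (spectral profile and scalar traits) -> sister-pair
extraction and one-way ANOVA -> Pagel's lambda fits under the equal and
proportional branch-length hypotheses -> museum-storage tests -> sampling
randomization.  Every stage writes a CSV/JSON artefact into the output
directory, and the run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import colorimetry, comparative, phylo_signal, spectra, visual_model
from .comparative import StoragePair, TaxonomyTable
from .phylo_signal import apply_branch_scheme, fit_lambda, fits_to_frame
from .spectra import GridSpectrum, hierarchical_mean
from .synthetic_data import GeneratorConfig, SyntheticDataset, generate_dataset
from .variance_partition import scalar_partition, variance_profile
from .visual_model import Illuminant, NoiseModel, build_sensitivities

log = logging.getLogger("eggcolor")

LAMBDA_TRAITS = ("luminance", "X", "Y", "Z")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """What to run and where to write it."""

    output_dir: str | Path = "results"
    seed: int = 0
    generator: GeneratorConfig | None = None
    spectra_path: str | None = None
    tree_path: str | None = None
    taxonomy_path: str | None = None
    years_path: str | None = None
    maculation_path: str | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    boundaries: colorimetry.RegionBoundaries = field(
        default_factory=colorimetry.RegionBoundaries
    )
    lambda_schemes: tuple = ("equal", "proportional")
    randomization_reps: int = 1000

    def __post_init__(self) -> None:
        if self.generator is None and self.spectra_path is None:
            raise PipelineError(
                "config must supply either a generator config or input paths"
            )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def build_storage_pairs(
    grid: list[GridSpectrum], years: pd.DataFrame
) -> list[StoragePair]:
    """Oldest/newest clutch pair per species, with clutch-average deltas.

    Luminance deltas and spectral-shape deltas are computed between the
    clutch-average spectra (averaged over eggs, then replicates) of the two
    clutches with the largest separation in collection year; species with
    fewer than two distinct collection years are skipped.
    """
    clutch_means = hierarchical_mean(grid, ["family", "species", "clutch_id"])
    ymap = {
        (r.family, r.species, r.clutch_id): int(r.collection_year)
        for r in years.itertuples()
    }
    by_species: dict[tuple, list] = {}
    for key, spec in clutch_means.items():
        if key not in ymap:
            continue
        by_species.setdefault(key[:2], []).append((ymap[key], key, spec))
    pairs = []
    for (fam, sp), entries in sorted(by_species.items()):
        if len(entries) < 2:
            continue
        entries.sort(key=lambda e: (e[0], e[1]))
        (y_old, _, s_old), (y_new, _, s_new) = entries[0], entries[-1]
        if y_new == y_old:
            continue
        pairs.append(
            StoragePair(
                species=sp,
                year_old=y_old,
                year_new=y_new,
                delta_luminance=colorimetry.luminance(s_new)
                - colorimetry.luminance(s_old),
                delta_spectral=spectra.abs_sum_difference(s_new, s_old),
            )
        )
    return pairs


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": []}

    # -- ingest or generate ------------------------------------------------
    if cfg.generator is not None:
        gen = GeneratorConfig(**{**cfg.generator.__dict__, "seed": cfg.seed})
        ds: SyntheticDataset = generate_dataset(gen)
        raw = ds.raw_spectra
        tree = ds.tree
        taxonomy = TaxonomyTable.from_frame(ds.taxonomy)
        years = ds.years
        maculation = ds.maculation
        report["n_species_truth"] = len(ds.truth["trait_by_species"])
    else:
        raw = spectra.read_spectra_table(cfg.spectra_path)
        tree = (
            phylo_signal.read_newick_tree(cfg.tree_path)
            if cfg.tree_path
            else None
        )
        taxonomy = (
            TaxonomyTable.from_frame(pd.read_csv(cfg.taxonomy_path))
            if cfg.taxonomy_path
            else None
        )
        years = pd.read_csv(cfg.years_path) if cfg.years_path else None
        maculation = (
            pd.read_csv(cfg.maculation_path) if cfg.maculation_path else None
        )
    report["n_raw_spectra"] = len(raw)
    report["stages"].append("ingest")

    # -- grid + colour statistics -----------------------------------------
    grid = [_stage("resample")(spectra.resample_to_grid)(r) for r in raw]
    sens = build_sensitivities("template")
    ill = Illuminant()
    meta = pd.DataFrame(
        {
            "family": [s.meta.family for s in grid],
            "species": [s.meta.species for s in grid],
            "clutch_id": [s.meta.clutch_id for s in grid],
            "egg_id": [s.meta.egg_id for s in grid],
        }
    )
    lum = np.array([colorimetry.luminance(s) for s in grid])
    bright = np.array([colorimetry.brightness(s) for s in grid])
    loci = [
        visual_model.chromatic_locus(
            visual_model.quantum_catches(s, sens, ill), cfg.noise
        )
        for s in grid
    ]
    obs = meta.assign(
        luminance=lum,
        brightness=bright,
        X=[l.X for l in loci],
        Y=[l.Y for l in loci],
        Z=[l.Z for l in loci],
    )
    obs.to_csv(out / "observations.csv", index=False)
    report["stages"].append("colour")

    # species means (replicates -> egg -> clutch -> species)
    sp_means = hierarchical_mean(grid, ["family", "species"])
    species_rows = []
    species_loci: dict[str, list] = {}
    sp_mean_locus: dict[str, visual_model.ChromaticLocus] = {}
    for (fam, sp), smean in sorted(sp_means.items()):
        locus = visual_model.chromatic_locus(
            visual_model.quantum_catches(smean, sens, ill), cfg.noise
        )
        sp_mean_locus[sp] = locus
        region = colorimetry.classify_max_region(smean, cfg.boundaries)
        species_rows.append(
            {
                "family": fam,
                "species": sp,
                "luminance": colorimetry.luminance(smean),
                "brightness": colorimetry.brightness(smean),
                "X": locus.X,
                "Y": locus.Y,
                "Z": locus.Z,
                "max_region": region,
            }
        )
    species_df = pd.DataFrame(species_rows)
    species_df.to_csv(out / "species_summary.csv", index=False)
    report["pct_lws_max"] = float(
        (species_df["max_region"] == "LWS").mean() * 100.0
    )
    for s, l in zip(obs["species"], loci):
        species_loci.setdefault(s, []).append(l)
    median_locus, frac = visual_model.jnd_summary(species_loci)
    report["median_locus"] = {
        "X": median_locus.X,
        "Y": median_locus.Y,
        "Z": median_locus.Z,
    }
    report["pct_within_1jnd"] = frac * 100.0
    report["stages"].append("jnd_summary")

    # -- variance partitioning --------------------------------------------
    profile = _stage("variance_profile")(variance_profile)(grid)
    profile.to_frame().to_csv(out / "variance_profile.csv", index=False)
    traits = {
        "luminance": lum,
        "X": obs["X"].to_numpy(),
        "Y": obs["Y"].to_numpy(),
        "Z": obs["Z"].to_numpy(),
    }
    scalar = _stage("scalar_partition")(scalar_partition)(meta, traits)
    scalar.to_csv(out / "scalar_partition.csv", index=False)
    report["stages"].append("variance_partition")

    # -- sister pairs -------------------------------------------------------
    if taxonomy is not None:
        rel_means = {
            sp: smean for (_, sp), smean in sp_means.items()
        }
        pairs, leftover = comparative.extract_sister_pairs(taxonomy)
        pairs = [
            comparative.SisterPair(
                p.species_a,
                p.species_b,
                p.level,
                spectra.abs_sum_difference(
                    rel_means[p.species_a], rel_means[p.species_b]
                ),
            )
            for p in pairs
        ]
        pd.DataFrame(
            [
                {
                    "species_a": p.species_a,
                    "species_b": p.species_b,
                    "level": p.level,
                    "spectral_difference": p.spectral_difference,
                }
                for p in pairs
            ]
        ).to_csv(out / "sister_pairs.csv", index=False)
        try:
            anova = comparative.sister_pair_anova(pairs)
            report["sister_pair_anova"] = {
                "F": anova.F,
                "df": [anova.df_between, anova.df_within],
                "p": anova.p,
            }
        except comparative.ComparativeError as exc:
            report["sister_pair_anova"] = {"skipped": str(exc)}
        report["n_sister_pairs"] = len(pairs)
        report["n_unpaired"] = len(leftover)
        mdw = colorimetry.fraction_max_diff_in_interval(
            [
                (rel_means[p.species_a], rel_means[p.species_b])
                for p in pairs
            ],
            400.0,
            500.0,
        )
        report["frac_max_diff_400_500"] = mdw
        report["stages"].append("sister_pairs")

    # -- phylogenetic signal ------------------------------------------------
    if tree is not None:
        fits = {}
        sp_lum = species_df.set_index("species")["luminance"].to_dict()
        trait_maps = {
            "luminance": sp_lum,
            "X": {s: l.X for s, l in sp_mean_locus.items()},
            "Y": {s: l.Y for s, l in sp_mean_locus.items()},
            "Z": {s: l.Z for s, l in sp_mean_locus.items()},
        }
        for scheme in cfg.lambda_schemes:
            t = apply_branch_scheme(tree, scheme)
            C, order = phylo_signal.phylo_covariance(t)
            for name in LAMBDA_TRAITS:
                y = np.array([trait_maps[name][s] for s in order])
                fits[f"{name}:{scheme}"] = fit_lambda(
                    y, C=C, tip_order=order, scheme=scheme
                )
        lam_df = fits_to_frame(fits)
        lam_df["trait"] = [k.split(":")[0] for k in fits]
        lam_df.to_csv(out / "lambda_summary.csv", index=False)
        report["lambda"] = {
            k: round(v.lambda_hat, 4) for k, v in fits.items()
        }
        report["stages"].append("lambda")

    # -- storage tests -------------------------------------------------------
    if years is not None:
        storage = build_storage_pairs(grid, years)
        if len(storage) >= 3:
            res = comparative.storage_effect_tests(storage)
            report["storage"] = {
                "paired_t": res.paired_t,
                "paired_p": res.paired_p,
                "n": res.n,
                "spectral_slope": res.spectral_on_log_years.estimate,
                "spectral_slope_p": res.spectral_on_log_years.p,
                "luminance_slope": res.luminance_on_log_years.estimate,
            }
        else:
            report["storage"] = {"skipped": "fewer than 3 usable pairs"}
        report["stages"].append("storage")

    # -- maculation + randomization -----------------------------------------
    if maculation is not None:
        rep = comparative.maculation_repeatability(maculation)
        report["maculation_r"] = rep.observer_correlation
        imm = rep.species_scores[rep.species_scores < 0.5].index
        pool = species_df.set_index("species")["luminance"]
        focal = pool.reindex(imm).dropna()
        if len(focal) >= 2 and len(pool) > len(focal):
            rand = comparative.sampling_randomization(
                pool.to_numpy(),
                focal.to_numpy(),
                reps=cfg.randomization_reps,
                seed=np.random.default_rng(cfg.seed),
            )
            report["randomization"] = {
                "observed_median": rand.observed_median,
                "envelope": [rand.envelope_low, rand.envelope_high],
                "inside": rand.inside,
            }
        report["stages"].append("randomization")

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    log.info("pipeline complete: %s", ", ".join(report["stages"]))
    return report
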