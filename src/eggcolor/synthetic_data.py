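"""Synthetic eggshell-colour studies with known ground truth.

The generator emulates the structure of a museum eggshell dataset: a
phylogeny whose top-level clades are families, species-level pigment
concentrations (biliverdin = blue-green, protoporphyrin = red-brown) driven
by a lambda-structured trait evolving on that tree, nested clutch/egg/
replicate perturbations sized to configured variance fractions, raw spectra
at ~0.4 nm resolution, collection years with an optional ln(age) storage
drift, and two-observer three-point maculation scores.

Ground truth (lambda, variance fractions, concentrations, drift) is stored
with every dataset so each pipeline stage has a recovery test.

Design notes
------------
The species-level trait is a single draw from N(0, C_lambda) on a two-layer
tree (family stems joined at the root, pure-birth subtrees within families,
unit tip depth), so the split of species-level variance between the family
and species-within-family strata is controlled through the family stem
length, which is solved from the configured fractions given lambda and the
realized within-family shared depth.  This requires lambda >= the targeted
between-family share; infeasible combinations raise.  Clutch, egg and
replicate effects are mean-one lognormal gains on the whole spectrum (plus
a small white measurement-noise floor at the raw step), calibrated in
luminance units so that a nested ANOVA of luminance recovers the configured
fractions; species spectra are additionally rescaled (shape-preserving) so
the family/species split matches the configured fractions in realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.special import expit

from .comparative import StoragePair
from .phylo_signal import Phylo, phylo_covariance
from .spectra import GRID_NM, GridSpectrum, RawSpectrum, SampleKey, resample_to_grid

LUM_MASK = (GRID_NM >= 500.0) & (GRID_NM <= 700.0)


class GeneratorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Trees and traits


def simulate_tree(
    n_tips: int,
    seed: int | np.random.Generator = 0,
    birth_rate: float = 1.0,
    prefix: str = "t",
) -> Phylo:
    """Pure-birth (Yule) tree by iterative random tip splitting.

    Waiting times between splits are exponential with rate k * birth_rate
    (k = current tip count); a final waiting time after the last split makes
    the tree ultrametric.
    """
    if n_tips < 2:
        raise GeneratorError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    tips = []
    for _ in range(2):
        child = root.new_child(edge_length=0.0)
        tips.append(child)
    k = 2
    while True:
        dt = rng.exponential(1.0 / (k * birth_rate))
        for tip in tips:
            tip.edge.length += dt
        if k == n_tips:
            break
        idx = int(rng.integers(k))
        parent = tips.pop(idx)
        for _ in range(2):
            child = parent.new_child(edge_length=0.0)
            tips.append(child)
        k += 1
    for i, tip in enumerate(tips, start=1):
        tip.taxon = taxa.new_taxon(label=f"{prefix}{i:04d}")
    return Phylo(tree=tree, scheme="as-given")


def simulate_traits(
    phylo: Phylo | np.ndarray,
    sigma2: float,
    lambda_true: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw tip values from N(0, sigma2 * C_lambda) via an eigendecomposition.

    ``phylo`` may be a tree or a precomputed covariance matrix; values are
    returned in sorted-tip-label order (matrix row order otherwise).
    """
    if not 0.0 <= lambda_true <= 1.0:
        raise GeneratorError("lambda_true must lie in [0, 1]")
    if sigma2 <= 0:
        raise GeneratorError("sigma2 must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = phylo if isinstance(phylo, np.ndarray) else phylo_covariance(phylo)[0]
    Cl = C * lambda_true
    np.fill_diagonal(Cl, np.diag(C))
    w, V = np.linalg.eigh(Cl)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise GeneratorError("lambda-transformed covariance is not PSD")
    w = np.clip(w, 0.0, None)
    return V @ (np.sqrt(sigma2 * w) * rng.standard_normal(len(w)))


# ---------------------------------------------------------------------------
# Pigment spectra


@dataclass(frozen=True)
class PigmentParams:
    """Concentrations of the two eggshell tetrapyrroles plus baseline shape.

    The reflectance model is R(l) = baseline(l) * exp(-c_bv * A_bv(l)
    - c_pp * A_pp(l)): a smooth baseline rising to ~70% at 700 nm, a
    biliverdin absorbance with bands near 380 and 670 nm (blue-green
    reflectance when concentrated), and a protoporphyrin absorbance with a
    strong Soret-like band at 410 nm plus weaker bands at 540/580 nm
    (red-brown reflectance).  Band centres/widths are documented defaults,
    not fits to published pigment curves.
    """

    biliverdin_conc: float = 0.0
    protoporphyrin_conc: float = 0.0
    baseline_max: float = 70.0
    baseline_mid_nm: float = 450.0
    baseline_scale_nm: float = 80.0
    bv_bands: tuple = ((380.0, 40.0, 1.0), (670.0, 50.0, 0.8))
    pp_bands: tuple = ((410.0, 30.0, 1.0), (540.0, 25.0, 0.4), (580.0, 25.0, 0.4))

    def __post_init__(self) -> None:
        if self.biliverdin_conc < 0 or self.protoporphyrin_conc < 0:
            raise GeneratorError("pigment concentrations must be >= 0")


def _bands(wl: np.ndarray, bands) -> np.ndarray:
    out = np.zeros_like(wl, dtype=float)
    for centre, width, weight in bands:
        out += weight * np.exp(-0.5 * ((wl - centre) / width) ** 2)
    return out


def pigment_reflectance(
    wl: np.ndarray,
    c_bv: float | np.ndarray,
    c_pp: float | np.ndarray,
    params: PigmentParams | None = None,
) -> np.ndarray:
    """Continuous pigment reflectance model on arbitrary wavelengths (%).

    Vectorised over concentrations: if c_bv/c_pp are length-m arrays the
    result has shape (m, len(wl)).
    """
    p = params or PigmentParams()
    base = p.baseline_max * expit((wl - p.baseline_mid_nm) / p.baseline_scale_nm)
    absorb = (
        np.multiply.outer(np.asarray(c_bv, float), _bands(wl, p.bv_bands))
        + np.multiply.outer(np.asarray(c_pp, float), _bands(wl, p.pp_bands))
    )
    return base * np.exp(-absorb)


def pigment_spectrum(params: PigmentParams) -> GridSpectrum:
    """Pigment reflectance model evaluated on the canonical 5-nm grid."""
    vals = pigment_reflectance(
        GRID_NM, params.biliverdin_conc, params.protoporphyrin_conc, params
    )
    return GridSpectrum(reflectance_pct=np.atleast_2d(vals)[0])


# ---------------------------------------------------------------------------
# Full datasets


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of a synthetic museum dataset.

    Defaults mirror the emulated sampling design: up to 5 clutches per
    species and 5 eggs per clutch, 6 replicate measures per egg, collection
    years spanning 1825-2002, and raw spectra at 0.4 nm steps.  Variance
    fractions are ordered (family, species, clutch, egg, replicate) and are
    the target shares of luminance variance at each nested level.
    """

    n_families: int = 10
    species_per_family: int = 5
    clutches_per_species: int = 3
    eggs_per_clutch: int = 3
    replicates_per_egg: int = 6
    variance_fractions: tuple = (0.25, 0.25, 0.125, 0.125, 0.25)
    lambda_true: float = 0.7
    trait_slope: float = 0.5  # logistic squashing slope, trait -> concentration
    trait_offset: float = -1.5  # shifts the map toward low-pigment (brown/white) eggs
    bv_range: tuple = (0.0, 2.2)
    pp_range: tuple = (1.5, 0.0)  # decreasing in the trait: blue <-> brown axis
    noise_floor_pct: float = 0.5  # white measurement noise SD at the raw step
    year_range: tuple = (1825, 2002)
    drift_coefficient: float = 0.0
    maculation_probs: tuple = (0.37, 0.33, 0.30)
    observer_flip_prob: float = 0.05
    raw_step_nm: float = 0.4
    raw_span_nm: tuple = (298.0, 702.0)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_families,
            self.species_per_family,
            self.clutches_per_species,
            self.eggs_per_clutch,
            self.replicates_per_egg,
        )
        if any(c < 1 for c in counts):
            raise GeneratorError("all design counts must be >= 1")
        if self.clutches_per_species > 5 or self.eggs_per_clutch > 5:
            raise GeneratorError("at most 5 clutches/species and 5 eggs/clutch")
        vf = np.asarray(self.variance_fractions, float)
        if len(vf) != 5 or np.any(vf < 0) or vf.sum() > 1.0 + 1e-9:
            raise GeneratorError(
                "variance_fractions must be 5 nonnegative values summing to <= 1"
            )
        if not 0.0 <= self.lambda_true <= 1.0:
            raise GeneratorError("lambda_true must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    """A complete synthetic study plus its ground-truth record."""

    tree: Phylo
    taxonomy: pd.DataFrame  # species, genus, tribe, subfamily, family
    raw_spectra: list[RawSpectrum]
    years: pd.DataFrame  # family, species, clutch_id, collection_year
    maculation: pd.DataFrame  # species, egg_id, observer_a, observer_b
    truth: dict

    def grid_spectra(self) -> list[GridSpectrum]:
        return [resample_to_grid(r) for r in self.raw_spectra]


def _family_tree(
    n_families: int,
    species_per_family: int,
    stem_fraction: float,
    rng: np.random.Generator,
) -> tuple[Phylo, pd.DataFrame, float]:
    """Two-layer tree: family stems from the root, Yule subtrees within.

    Returns the tree, the taxonomy table, and the realized mean shared-depth
    fraction of within-family species pairs (measured below the family node,
    as a fraction of total depth 1).
    """
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    t_f = stem_fraction
    t_w = 1.0 - t_f
    shared_fracs = []
    rows = []
    for fam in range(1, n_families + 1):
        fam_name = f"F{fam:02d}"
        if species_per_family == 1:
            sp = f"{fam_name}_sp01"
            node = tree.seed_node.new_child(edge_length=1.0)
            node.taxon = taxa.new_taxon(label=sp)
            rows.append((sp, fam_name))
            continue
        sub = simulate_tree(species_per_family, rng, prefix=f"{fam_name}_sp")
        # scale the subtree to height t_w
        depths = [
            leaf.distance_from_root() for leaf in sub.tree.leaf_node_iter()
        ]
        height = depths[0]
        factor = t_w / height if height > 0 else 0.0
        for edge in sub.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        # mean shared depth among within-family pairs, as fraction of 1
        Csub, _ = phylo_covariance(sub)
        m = len(Csub)
        off = (Csub.sum() - np.trace(Csub)) / (m * (m - 1))
        shared_fracs.append(off + 0.0)  # below-family shared depth (already scaled)
        fam_node = tree.seed_node.new_child(edge_length=t_f)
        for node in sub.tree.seed_node.child_nodes():
            fam_node.add_child(node)
        for leaf in sub.tree.leaf_node_iter():
            label = leaf.taxon.label
            leaf.taxon = taxa.new_taxon(label=label)
            rows.append((label, fam_name))
    taxonomy = pd.DataFrame(rows, columns=["species", "family"])
    # intermediate ranks: consecutive species within a family are grouped
    # pairwise into genera, genera pairwise into tribes, tribes pairwise
    # into subfamilies (nesting-consistent by construction)
    within_idx = taxonomy.groupby("family").cumcount()
    taxonomy["genus"] = [
        f"{fam}_g{int(i) // 2 + 1:02d}"
        for fam, i in zip(taxonomy["family"], within_idx)
    ]
    taxonomy["tribe"] = [
        f"{fam}_t{int(i) // 4 + 1:02d}"
        for fam, i in zip(taxonomy["family"], within_idx)
    ]
    taxonomy["subfamily"] = [
        f"{fam}_sf{int(i) // 8 + 1:02d}"
        for fam, i in zip(taxonomy["family"], within_idx)
    ]
    mean_shared = float(np.mean(shared_fracs)) if shared_fracs else 0.0
    return Phylo(tree=tree, scheme="as-given"), taxonomy, mean_shared


def _solve_stem_fraction(
    target_between: float, lam: float, shared_frac_unit: float
) -> float:
    """Family stem length t_f with lam * (t_f + (1 - t_f) * s) = target."""
    if target_between <= 0.0:
        return 0.0
    if lam <= 0.0:
        raise GeneratorError(
            "between-family variance requires lambda_true > 0 "
            "(family structure is carried by the tree)"
        )
    s = shared_frac_unit
    t_f = (target_between / lam - s) / (1.0 - s) if s < 1.0 else 1.0
    if not -1e-9 <= t_f <= 1.0 + 1e-9:
        raise GeneratorError(
            f"infeasible variance fractions: between-family share "
            f"{target_between:.3f} not reachable with lambda_true={lam} "
            f"(achievable range [{lam * s:.3f}, {lam:.3f}])"
        )
    return float(np.clip(t_f, 0.0, 1.0))


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate a full synthetic study; deterministic under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    vf = np.asarray(cfg.variance_fractions, float)
    f_fam, f_sp, f_cl, f_egg, f_rep = vf
    sp_level = f_fam + f_sp

    # -- tree and species trait -------------------------------------------
    target_between = f_fam / sp_level if sp_level > 0 else 0.0
    # provisional subtree draw to measure the shared-depth fraction, then the
    # stem length is solved and the same subtrees reused via a fresh seed
    sub_seed = int(rng.integers(2**31 - 1))
    probe_tree, _, shared_w = _family_tree(
        cfg.n_families, cfg.species_per_family, 0.5, np.random.default_rng(sub_seed)
    )
    # shared_w was measured on subtrees scaled to height 0.5; rescale to unit
    shared_unit = shared_w / 0.5 if cfg.species_per_family > 1 else 0.0
    if sp_level > 0:
        t_f = _solve_stem_fraction(target_between, cfg.lambda_true, shared_unit)
    else:
        t_f = 0.5
    tree, taxonomy, _ = _family_tree(
        cfg.n_families, cfg.species_per_family, t_f, np.random.default_rng(sub_seed)
    )
    species = taxonomy["species"].tolist()
    n_species = len(species)
    C, tip_order = phylo_covariance(tree)
    assert tip_order == sorted(species)
    if sp_level > 0 and n_species > 1:
        z = simulate_traits(C, 1.0, cfg.lambda_true, rng)
    else:
        z = np.zeros(n_species)
    z_by_species = dict(zip(tip_order, z))

    # -- species spectra ---------------------------------------------------
    pp = PigmentParams()
    zs = np.array([z_by_species[s] for s in species])
    squash = expit(cfg.trait_slope * zs + cfg.trait_offset)
    c_bv = cfg.bv_range[0] + (cfg.bv_range[1] - cfg.bv_range[0]) * squash
    c_pp = cfg.pp_range[0] + (cfg.pp_range[1] - cfg.pp_range[0]) * squash
    wl = np.arange(cfg.raw_span_nm[0], cfg.raw_span_nm[1] + 1e-9, cfg.raw_step_nm)
    base_raw = pigment_reflectance(wl, c_bv, c_pp, pp)  # (n_species, n_wl)
    lum_cols = (wl >= 500.0) & (wl <= 700.0)

    # luminance of the species spectra (approximated on the raw grid,
    # rescaled to the 41-point 5-nm sum) for variance calibration
    lum_sp = base_raw[:, lum_cols].mean(axis=1) * 41.0

    # Realization-level calibration: rescale each species spectrum by a
    # positive factor so the one-way (family / species-within-family)
    # decomposition of species luminance matches the configured split
    # exactly.  Scaling a spectrum leaves its shape (relative spectrum and
    # chromatic locus) untouched, so the lambda-structured trait still
    # drives the chromatic axes; only the achromatic variance budget is
    # pinned down.
    fam_codes = pd.factorize(taxonomy["family"])[0]
    if sp_level > 0 and n_species > 1 and cfg.species_per_family > 1:
        grand = lum_sp.mean()
        fam_means = np.bincount(fam_codes, weights=lum_sp) / np.bincount(fam_codes)
        m = cfg.species_per_family
        msb = m * np.sum((fam_means - grand) ** 2) / max(cfg.n_families - 1, 1)
        msw = np.sum((lum_sp - fam_means[fam_codes]) ** 2) / (
            n_species - cfg.n_families
        )
        comp_fam_nat = max((msb - msw) / m, 0.0)
        total_var = (comp_fam_nat + msw) / sp_level
        b2 = f_sp * total_var / msw if msw > 0 else 0.0
        a2 = (m * f_fam + f_sp) * total_var / msb if msb > 0 else 0.0
        lum_target = (
            grand
            + np.sqrt(a2) * (fam_means[fam_codes] - grand)
            + np.sqrt(b2) * (lum_sp - fam_means[fam_codes])
        )
        scale = np.clip(lum_target / lum_sp, 0.05, None)
        base_raw = base_raw * scale[:, None]
        lum_sp = lum_sp * scale
    else:
        total_var = (0.05 * float(np.mean(lum_sp))) ** 2  # nominal scale

    # Clutch, egg and replicate effects are mean-one lognormal gains on the
    # whole spectrum; their variances are nested-corrected so the expected
    # luminance variance contribution of each level is exactly its fraction.
    mean_sq_lum = float(np.mean(lum_sp**2))
    v_cl = f_cl * total_var / mean_sq_lum
    v_egg = f_egg * total_var / (mean_sq_lum * (1.0 + v_cl))
    v_rep = f_rep * total_var / (mean_sq_lum * (1.0 + v_cl) * (1.0 + v_egg))

    def _lognorm_sigma(v: float) -> float:
        return float(np.sqrt(np.log1p(v))) if v > 0 else 0.0

    sd_floor_raw = cfg.noise_floor_pct

    # -- maculation (species level, scales replicate noise) ----------------
    mac_sp = rng.choice(3, size=n_species, p=np.asarray(cfg.maculation_probs))
    mac_by_species = dict(zip(species, mac_sp))
    noise_factor = {0: 0.8, 1: 1.0, 2: 1.2}
    # replicate-variance weights, mean-one over the (balanced) egg set so the
    # overall replicate fraction is preserved
    nf2 = np.array([noise_factor[m] ** 2 for m in mac_sp])
    w_mac = dict(zip(species, nf2 / nf2.mean()))

    # -- assemble observations --------------------------------------------
    years_rows = []
    mac_rows = []
    raw_spectra: list[RawSpectrum] = []
    obs_gain = []
    obs_species_idx = []
    obs_meta: list[SampleKey] = []
    drift_gain = []
    ref_year = cfg.year_range[1]
    tilt = (wl - 500.0) / 200.0

    sp_index = {s: i for i, s in enumerate(species)}
    sig_cl = _lognorm_sigma(v_cl)
    sig_egg = _lognorm_sigma(v_egg)

    def _gain(sigma: float) -> float:
        if sigma == 0.0:
            return 1.0
        return float(np.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0))

    for _, row in taxonomy.iterrows():
        sp, fam = row["species"], row["family"]
        sig_rep = _lognorm_sigma(v_rep * w_mac[sp])
        for ci in range(1, cfg.clutches_per_species + 1):
            clutch_id = f"{sp}_c{ci}"
            year = int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1))
            years_rows.append((fam, sp, clutch_id, year))
            g_clutch = _gain(sig_cl)
            age = ref_year - year + 1
            drift = cfg.drift_coefficient * np.log(age)
            for ei in range(1, cfg.eggs_per_clutch + 1):
                egg_id = f"{clutch_id}_e{ei}"
                mac_true = mac_by_species[sp]
                obs_a = mac_true
                obs_b = mac_true
                if rng.random() < cfg.observer_flip_prob:
                    obs_b = int(np.clip(mac_true + rng.choice([-1, 1]), 0, 2))
                mac_rows.append((sp, egg_id, obs_a, obs_b))
                g_egg = _gain(sig_egg)
                for ri in range(1, cfg.replicates_per_egg + 1):
                    obs_gain.append(g_clutch * g_egg * _gain(sig_rep))
                    obs_species_idx.append(sp_index[sp])
                    drift_gain.append(drift)
                    obs_meta.append(
                        SampleKey(
                            family=fam,
                            species=sp,
                            clutch_id=clutch_id,
                            egg_id=egg_id,
                            replicate_idx=ri,
                            collection_year=year,
                        )
                    )
    obs_gain = np.asarray(obs_gain)
    obs_species_idx = np.asarray(obs_species_idx)
    drift_gain = np.asarray(drift_gain)

    signal = base_raw[obs_species_idx] * (
        obs_gain[:, None] * (1.0 + drift_gain[:, None] * tilt[None, :])
    )
    refl = signal + rng.standard_normal(signal.shape) * sd_floor_raw
    for i, meta in enumerate(obs_meta):
        raw_spectra.append(
            RawSpectrum(wavelengths_nm=wl, reflectance_pct=refl[i], meta=meta)
        )

    truth = {
        "lambda_true": cfg.lambda_true,
        "variance_fractions": tuple(map(float, vf)),
        "stem_fraction": t_f,
        "trait_by_species": z_by_species,
        "biliverdin_by_species": dict(zip(species, map(float, c_bv))),
        "protoporphyrin_by_species": dict(zip(species, map(float, c_pp))),
        "maculation_by_species": {s: int(m) for s, m in mac_by_species.items()},
        "drift_coefficient": cfg.drift_coefficient,
        "seed": cfg.seed,
    }
    return SyntheticDataset(
        tree=tree,
        taxonomy=taxonomy[["species", "genus", "tribe", "subfamily", "family"]],
        raw_spectra=raw_spectra,
        years=pd.DataFrame(
            years_rows, columns=["family", "species", "clutch_id", "collection_year"]
        ),
        maculation=pd.DataFrame(
            mac_rows, columns=["species", "egg_id", "observer_a", "observer_b"]
        ),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Focused simulators for individual analysis stages


def simulate_nested_gaussian(
    n_per_level: tuple[int, int, int, int, int],
    component_variances: tuple[float, float, float, float, float],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Balanced five-level hierarchical Gaussian data with known components.

    ``n_per_level`` is (families, species/family, clutches/species,
    eggs/clutch, replicates/egg); component variances are ordered the same
    way with the replicate variance last.  Returns a DataFrame with design
    columns and a ``value`` column.
    """
    a, b, c, d, r = n_per_level
    v = np.asarray(component_variances, float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eff_f = rng.normal(0, np.sqrt(v[0]), a)
    eff_s = rng.normal(0, np.sqrt(v[1]), (a, b))
    eff_c = rng.normal(0, np.sqrt(v[2]), (a, b, c))
    eff_e = rng.normal(0, np.sqrt(v[3]), (a, b, c, d))
    eff_r = rng.normal(0, np.sqrt(v[4]), (a, b, c, d, r))
    total = (
        eff_f[:, None, None, None, None]
        + eff_s[:, :, None, None, None]
        + eff_c[:, :, :, None, None]
        + eff_e[:, :, :, :, None]
        + eff_r
    )
    idx = np.indices((a, b, c, d, r)).reshape(5, -1)
    return pd.DataFrame(
        {
            "family": [f"F{i}" for i in idx[0]],
            "species": [f"F{i}_s{j}" for i, j in zip(idx[0], idx[1])],
            "clutch_id": [
                f"F{i}_s{j}_c{k}" for i, j, k in zip(idx[0], idx[1], idx[2])
            ],
            "egg_id": [
                f"F{i}_s{j}_c{k}_e{l}"
                for i, j, k, l in zip(idx[0], idx[1], idx[2], idx[3])
            ],
            "replicate_idx": idx[4] + 1,
            "value": total.ravel(),
        }
    )


def simulate_storage_pairs(
    n_pairs: int,
    spectral_slope: float = 0.004,
    luminance_slope: float = 0.0,
    spectral_noise_sd: float = 0.01,
    luminance_noise_sd: float = 2.0,
    year_range: tuple[int, int] = (1825, 2002),
    seed: int | np.random.Generator = 0,
) -> list[StoragePair]:
    """Old/new clutch pairs whose spectral delta drifts with ln(years apart).

    delta_spectral = intercept + spectral_slope * ln(delta_years) + noise,
    mirroring the regression the storage analysis fits.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        y_old = int(rng.integers(year_range[0], year_range[1] - 1))
        y_new = int(rng.integers(y_old + 1, year_range[1] + 1))
        dy = y_new - y_old
        d_spec = max(
            0.0,
            0.02
            + spectral_slope * np.log(dy)
            + rng.normal(0.0, spectral_noise_sd),
        )
        d_lum = luminance_slope * np.log(dy) + rng.normal(0.0, luminance_noise_sd)
        pairs.append(
            StoragePair(
                species=f"sp{i:03d}",
                year_old=y_old,
                year_new=y_new,
                delta_luminance=float(d_lum),
                delta_spectral=float(d_spec),
            )
        )
    return pairs
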