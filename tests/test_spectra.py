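"""Spectral ingestion, gridding, normalisation and the shape-difference statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eggcolor import (
    GeneratorConfig,
    RawSpectrum,
    SampleKey,
    abs_sum_difference,
    average_spectrum,
    generate_dataset,
    read_spectra_table,
    relative_spectrum,
    resample_to_grid,
    write_spectra_table,
)
from eggcolor.spectra import (
    GRID_NM,
    GridSpectrum,
    SpectraSchemaError,
    SpectraValueError,
    hierarchical_mean,
    spectra_to_table,
)

from conftest import grid_spec


# ---------------------------------------------------------------------------
# reading and writing


def _toy_table(path):
    wl = [300.0, 400.0, 500.0, 600.0, 700.0]
    rows = []
    for rep in (1, 2):
        for w in wl:
            rows.append(
                {
                    "wavelength_nm": w,
                    "reflectance_pct": 10.0 * rep + w / 100.0,
                    "family": "F1",
                    "species": "s1",
                    "clutch_id": "c1",
                    "egg_id": "e1",
                    "replicate_idx": rep,
                    "collection_year": 1900,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def test_read_groups_by_replicate(tmp_path):
    spectra = read_spectra_table(_toy_table(tmp_path / "toy.csv"))
    assert len(spectra) == 2
    assert all(len(s.wavelengths_nm) == 5 for s in spectra)
    assert {s.meta.replicate_idx for s in spectra} == {1, 2}
    assert spectra[0].meta.collection_year == 1900


def test_read_missing_column_names_it(tmp_path):
    path = _toy_table(tmp_path / "toy.csv")
    df = pd.read_csv(path).drop(columns=["reflectance_pct"])
    df.to_csv(path, index=False)
    with pytest.raises(SpectraSchemaError, match="reflectance_pct"):
        read_spectra_table(path)


def test_read_non_numeric_reports_line(tmp_path):
    path = _toy_table(tmp_path / "toy.csv")
    df = pd.read_csv(path)
    df["wavelength_nm"] = df["wavelength_nm"].astype(object)
    df.loc[3, "wavelength_nm"] = "oops"
    df.to_csv(path, index=False)
    with pytest.raises(SpectraSchemaError, match="line 5"):
        read_spectra_table(path)


def test_read_duplicate_wavelength_rejected(tmp_path):
    path = _toy_table(tmp_path / "toy.csv")
    df = pd.read_csv(path)
    df.loc[1, "wavelength_nm"] = 300.0
    df.to_csv(path, index=False)
    with pytest.raises(SpectraValueError, match="duplicate"):
        read_spectra_table(path)


def test_write_read_round_trip(tmp_path):
    ds = generate_dataset(
        GeneratorConfig(
            n_families=2,
            species_per_family=2,
            clutches_per_species=1,
            eggs_per_clutch=1,
            replicates_per_egg=2,
            raw_step_nm=2.0,
            seed=5,
        )
    )
    path = tmp_path / "spectra.csv"
    write_spectra_table(ds.raw_spectra, path)
    back = read_spectra_table(path)
    assert len(back) == len(ds.raw_spectra)
    orig = {
        (s.meta.species, s.meta.egg_id, s.meta.replicate_idx): s
        for s in ds.raw_spectra
    }
    for s in back:
        o = orig[(s.meta.species, s.meta.egg_id, s.meta.replicate_idx)]
        np.testing.assert_allclose(s.wavelengths_nm, o.wavelengths_nm)
        np.testing.assert_allclose(s.reflectance_pct, o.reflectance_pct)
    # second round trip is value-identical
    path2 = tmp_path / "again.csv"
    write_spectra_table(back, path2)
    assert spectra_to_table(back).equals(spectra_to_table(read_spectra_table(path2)))


# ---------------------------------------------------------------------------
# resampling


def test_resample_constant_is_invariant(constant_raw):
    g = resample_to_grid(constant_raw)
    assert len(g.reflectance_pct) == 81
    np.testing.assert_allclose(g.reflectance_pct, 50.0, atol=1e-9)


def test_resample_ramp_matches_analytic_window_means(key):
    wl = np.arange(300.0, 700.0 + 1e-9, 0.1)
    raw = RawSpectrum(wl, (wl - 300.0) / 4.0, key)
    g = resample_to_grid(raw)
    lo = np.maximum(GRID_NM - 2.5, 300.0)
    hi = np.minimum(GRID_NM + 2.5, 700.0)
    exact = ((lo + hi) / 2.0 - 300.0) / 4.0  # window mean of a linear ramp
    np.testing.assert_allclose(g.reflectance_pct, exact, atol=1e-9)


def test_resample_truncates_wide_range(key):
    wl = np.arange(250.0, 800.0 + 1e-9, 0.4)
    g = resample_to_grid(RawSpectrum(wl, np.full_like(wl, 30.0), key))
    assert len(g.reflectance_pct) == 81
    np.testing.assert_allclose(g.grid_nm[[0, -1]], [300.0, 700.0])


def test_resample_point_mode(key):
    wl = np.arange(300.0, 700.0 + 1e-9, 0.1)
    g = resample_to_grid(RawSpectrum(wl, (wl - 300.0) / 4.0, key), mode="point")
    np.testing.assert_allclose(g.reflectance_pct, (GRID_NM - 300.0) / 4.0, atol=1e-12)


def test_resample_rejects_gap_and_short_range(key):
    wl = np.concatenate([np.arange(300.0, 480.0, 0.4), np.arange(490.0, 700.1, 0.4)])
    with pytest.raises(SpectraValueError, match="gap"):
        resample_to_grid(RawSpectrum(wl, np.ones_like(wl), key))
    wl2 = np.arange(350.0, 700.1, 0.4)
    with pytest.raises(SpectraValueError, match="cover"):
        resample_to_grid(RawSpectrum(wl2, np.ones_like(wl2), key))


def test_negative_reflectance_clipped_before_averaging(key):
    wl = np.arange(300.0, 700.0 + 1e-9, 0.4)
    refl = np.full_like(wl, -5.0)
    refl[wl >= 500.0] = 20.0
    g = resample_to_grid(RawSpectrum(wl, refl, key))
    assert g.reflectance_pct.min() >= 0.0
    assert g.reflectance_pct[GRID_NM == 600.0][0] == pytest.approx(20.0)


# ---------------------------------------------------------------------------
# relative spectra and averaging


def test_relative_constant_is_uniform():
    r = relative_spectrum(grid_spec(np.full(81, 12.0)))
    np.testing.assert_allclose(r.proportions, 1.0 / 81.0)


def test_relative_scale_invariance(toy_grid):
    r1 = relative_spectrum(toy_grid)
    r2 = relative_spectrum(grid_spec(7.3 * toy_grid.reflectance_pct))
    np.testing.assert_allclose(r1.proportions, r2.proportions, atol=1e-12)


def test_relative_hand_example():
    v = np.zeros(81)
    v[[10, 20, 30]] = [10.0, 20.0, 70.0]
    r = relative_spectrum(grid_spec(v))
    np.testing.assert_allclose(r.proportions[[10, 20, 30]], [0.1, 0.2, 0.7])
    assert r.proportions.sum() == pytest.approx(1.0)


def test_relative_all_zero_errors():
    with pytest.raises(SpectraValueError, match="all-zero"):
        relative_spectrum(grid_spec(np.zeros(81)))


def test_average_identity_and_midpoint(toy_grid):
    same = average_spectrum([toy_grid, toy_grid, toy_grid])
    np.testing.assert_allclose(same.reflectance_pct, toy_grid.reflectance_pct)
    mid = average_spectrum(
        [grid_spec(np.full(81, 40.0)), grid_spec(np.full(81, 60.0))]
    )
    np.testing.assert_allclose(mid.reflectance_pct, 50.0)
    with pytest.raises(SpectraValueError):
        average_spectrum([])


def test_hierarchical_mean_is_nested_not_pooled():
    def k(egg, rep):
        return SampleKey("F", "s", "c", egg, rep)

    spectra = [
        grid_spec(np.full(81, 10.0), k("e1", 1)),
        grid_spec(np.full(81, 20.0), k("e1", 2)),
        grid_spec(np.full(81, 40.0), k("e2", 1)),
    ]
    sp_mean = hierarchical_mean(spectra, ["family", "species"])
    # egg means are 15 and 40; the species mean weights eggs equally: 27.5
    np.testing.assert_allclose(
        sp_mean[("F", "s")].reflectance_pct, 27.5
    )


# ---------------------------------------------------------------------------
# absolute sum difference


def test_abs_sum_difference_identity_and_bound(toy_grid):
    assert abs_sum_difference(toy_grid, toy_grid) == 0.0
    a = np.zeros(81)
    b = np.zeros(81)
    a[:40] = 1.0
    b[40:] = 1.0
    assert abs_sum_difference(grid_spec(a), grid_spec(b)) == pytest.approx(2.0)


def test_abs_sum_difference_matches_elementwise_loop():
    rng = np.random.default_rng(3)
    a = grid_spec(rng.uniform(0, 50, 81))
    b = grid_spec(rng.uniform(0, 50, 81))
    ra = a.reflectance_pct / a.reflectance_pct.sum()
    rb = b.reflectance_pct / b.reflectance_pct.sum()
    brute = sum(abs(x - y) for x, y in zip(ra, rb))
    assert abs_sum_difference(a, b) == pytest.approx(brute, abs=1e-12)


@settings(deadline=None, max_examples=25)
@given(
    c1=st.floats(0.1, 100.0),
    c2=st.floats(0.1, 100.0),
    seed=st.integers(0, 1000),
)
def test_abs_sum_difference_scaling_pseudometric(c1, c2, seed):
    """d(a, b) depends only on spectral shape: invariant to positive scaling."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.1, 50, 81)
    b = rng.uniform(0.1, 50, 81)
    d0 = abs_sum_difference(grid_spec(a), grid_spec(b))
    d1 = abs_sum_difference(grid_spec(c1 * a), grid_spec(c2 * b))
    assert d1 == pytest.approx(d0, abs=1e-9)
    assert 0.0 <= d1 <= 2.0
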