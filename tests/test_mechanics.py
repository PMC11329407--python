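import dataclasses

import numpy as np
import pytest
from lxml import etree

import kneedeg as kd
from kneedeg.mechanics import (
    FEMUR_PROPS,
    TIBIA_PROPS,
    ColumnLaw,
    tissue_stress,
)


def test_undeformed_column_is_stress_free():
    r = kd.column_response(0.0)
    assert r.pressure == 0.0
    assert r.sigma_femoral == 0.0
    assert r.sigma_tibial == 0.0


def test_column_pressure_strictly_increasing():
    law = ColumnLaw(FEMUR_PROPS, TIBIA_PROPS, 0.55)
    eps = np.linspace(1e-4, 0.6, 400)
    p = law.pressure(eps)
    assert np.all(np.diff(p) > 0)
    assert p[0] > 0


def test_softer_tibia_absorbs_larger_strain_share():
    r = kd.column_response(0.3, thickness_f=1.0, thickness_t=1.0)
    assert r.eps_tibial > r.eps_femoral
    # the matched pressures agree between the sub-columns
    pf = tissue_stress(r.eps_femoral, FEMUR_PROPS)[0]
    pt = tissue_stress(r.eps_tibial, TIBIA_PROPS)[0]
    assert pf == pytest.approx(pt, rel=1e-9)


def test_strain_cap_warns_and_saturates():
    with pytest.warns(UserWarning):
        r = kd.column_response(0.7)
    assert r.capped


def test_femoral_stiffer_at_equal_strain():
    """At an equal (not pressure-matched) strain split the femoral surface
    stress dominates: primary fibril stiffness 215 vs 32 MPa."""
    sf = tissue_stress(0.2, FEMUR_PROPS)[1]
    st = tissue_stress(0.2, TIBIA_PROPS)[1]
    assert sf > st


def test_zero_fibril_limit_is_pure_matrix():
    soft = dataclasses.replace(FEMUR_PROPS, xi_fp=0.0, xi_fs=0.0)
    eps = 0.25
    lam = 1.0 - eps
    mu = soft.E_nf / (2.0 * (1.0 + soft.nu_nf))
    expected = mu * (1.0 / lam - lam**2)
    assert tissue_stress(eps, soft)[1] == pytest.approx(expected, rel=1e-12)


def test_apex_gap_and_flexion_rollback(medial_template):
    cols0 = kd.build_columns(medial_template, 0.0)
    nx, nz = medial_template.nx, medial_template.nz
    gap0 = cols0.gap.reshape(nx, nz)
    i0, _ = np.unravel_index(np.argmin(gap0), gap0.shape)
    assert abs(i0 - nx / 2) <= 1  # apex column at the condyle center

    cols15 = kd.build_columns(medial_template, 15.0)
    gap15 = cols15.gap.reshape(nx, nz)
    i15, _ = np.unravel_index(np.argmin(gap15), gap15.shape)
    assert i15 < i0  # contact migrates posteriorly (-X)


def test_column_areas_tile_the_plateau(medial_template):
    cols = kd.build_columns(medial_template, 0.0)
    tib = medial_template.nodes[medial_template.tib_surface_nodes]
    width_x = tib[..., 0].max() - tib[..., 0].min()
    width_z = tib[..., 2].max() - tib[..., 2].min()
    assert cols.area.sum() == pytest.approx(width_x * width_z, rel=0.01)


def test_zero_force_frame(medial_template):
    cols = kd.build_columns(medial_template, 0.0)
    frame = kd.solve_contact_frame(cols, 0.0)
    assert frame.pressure.max() < 1e-9
    assert frame.residual < 1e-6


def test_force_monotonicity(medial_template):
    cols = kd.build_columns(medial_template, 5.0)
    prev_area, prev_sigma = 0.0, 0.0
    for force in (100.0, 200.0, 400.0, 800.0, 1600.0, 3200.0):
        frame = kd.solve_contact_frame(cols, force)
        assert frame.residual < 1e-6
        assert frame.contact_area >= prev_area - 1e-9
        assert frame.pressure.max() >= prev_sigma
        prev_area, prev_sigma = frame.contact_area, frame.pressure.max()


def test_excessive_force_names_frame(medial_template):
    cols = kd.build_columns(medial_template, 0.0)
    with pytest.raises(ValueError, match="capacity"):
        kd.solve_contact_frame(cols, 1e9)


def test_constant_loading_gives_identical_frames(medial_template, median_subject, gait_curve):
    base = kd.loading_5050(median_subject, gait_curve)
    const = dataclasses.replace(
        base,
        force_medial=np.full_like(base.force_medial, 500.0),
        flexion_deg=np.full_like(base.flexion_deg, 5.0),
    )
    field = kd.simulate_stance(medial_template, const)
    assert np.allclose(field.sigma_history, field.sigma_history[0])
    assert np.all(field.envelope[None, :] >= field.sigma_history - 1e-12)


def test_stance_equilibrium_residuals(medial_template, median_subject, gait_curve):
    loading = kd.loading_5050(median_subject, gait_curve)
    field = kd.simulate_stance(medial_template, loading)
    assert field.residual.max() < 1e-6
    assert field.envelope.max() > 0


def test_nn_loading_medializes_stress(
    medial_template, lateral_template, median_subject, gait_curve, trained_predictor
):
    """Network loading shifts the peak stresses to the medial compartment
    for a varus-aligned median subject."""
    loading = kd.loading_ls_peak_nn(median_subject, gait_curve, trained_predictor)
    medial = kd.simulate_stance(medial_template, loading)
    lateral = kd.simulate_stance(lateral_template, loading)
    assert medial.envelope.max() > lateral.envelope.max()


def test_depth_weight_attenuates_with_depth(medial_template, median_subject, gait_curve):
    loading = kd.loading_5050(median_subject, gait_curve)
    field = kd.simulate_stance(medial_template, loading)
    env = field.envelope
    tib = medial_template.tissue == "tibial_cartilage"
    surf = env[tib & (medial_template.layer_index == 0)].max()
    deep = env[tib & (medial_template.layer_index == 2)].max()
    assert deep == pytest.approx(0.25 * surf, rel=1e-9)


def test_solver_deck_export(tmp_path, medial_template, median_subject, gait_curve):
    loading = kd.loading_5050(median_subject, gait_curve)
    path = tmp_path / "deck.feb"
    kd.export_solver_deck(medial_template, loading, path)
    root = etree.parse(str(path)).getroot()
    materials = root.findall(".//material")
    assert len(materials) == 2
    perms = {
        m.get("name"): float(m.find("permeability/perm").text) for m in materials
    }
    assert perms["tibial_cartilage"] == 18.0
    assert perms["femoral_cartilage"] == 6.0
    m_vals = {
        m.get("name"): float(m.find("permeability/M").text) for m in materials
    }
    assert m_vals["tibial_cartilage"] == pytest.approx(15.24)
    assert m_vals["femoral_cartilage"] == pytest.approx(5.06)
    assert len(root.findall(".//node")) == len(medial_template.nodes)
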