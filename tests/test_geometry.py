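import dataclasses
from types import SimpleNamespace

import numpy as np
import pytest

import kneedeg as kd
from kneedeg.geometry import (
    TemplateConfig,
    aspect_ratios,
    corner_jacobians,
    scale_mesh,
)


def test_template_is_valid_and_fraction_configured(medial_template):
    jac = corner_jacobians(medial_template)
    assert jac.min() > 0
    t_f, t_t = medial_template.thickness_femoral, medial_template.thickness_tibial
    assert t_f / (t_f + t_t) == pytest.approx(0.55)
    assert np.all(kd.element_volumes(medial_template) > 0)


def test_lateral_compartment_less_congruent(medial_template, lateral_template):
    """The lateral condyle is more curved, so the gap opens faster off-apex."""

    def gap_growth(mesh):
        cols = kd.build_columns(mesh, 0.0)
        gap = cols.gap.reshape(mesh.nx, mesh.nz)
        apex = np.unravel_index(np.argmin(gap), gap.shape)
        return gap[apex[0] + 3, apex[1]] - gap[apex]

    assert gap_growth(lateral_template) > gap_growth(medial_template)


def test_volume_converges_under_refinement():
    coarse = kd.build_template("medial", TemplateConfig(nx=10, nz=8))
    fine = kd.build_template("medial", TemplateConfig(nx=20, nz=16))
    v_c = kd.element_volumes(coarse).sum()
    v_f = kd.element_volumes(fine).sum()
    assert abs(v_f - v_c) / v_c < 0.02


def test_identity_scaling_is_exact(medial_template, template_measurements):
    scaled = scale_mesh(
        medial_template, template_measurements, template_measurements, "fixed_ratio"
    )
    assert np.abs(scaled.nodes - medial_template.nodes).max() < 1e-12


def test_thickness_modes_coincide_at_template_fraction(
    medial_template, template_measurements
):
    """fixed_ratio and scaled_ratio agree exactly when the subject's femoral
    fraction equals the template's, for any other anatomy ratios."""
    subject = dataclasses.replace(
        template_measurements, icd=44.0, ap_medial=57.0, js_medial=5.5
    )
    a = scale_mesh(medial_template, template_measurements, subject, "fixed_ratio")
    b = scale_mesh(medial_template, template_measurements, subject, "scaled_ratio")
    assert np.array_equal(a.nodes, b.nodes)


def test_icd_scaling_halves_tibial_widths(medial_template, template_measurements):
    half = dataclasses.replace(template_measurements, icd=template_measurements.icd / 2)
    scaled = scale_mesh(medial_template, template_measurements, half, "fixed_ratio")
    tib = medial_template.node_tissue == "tibial_cartilage"
    assert np.allclose(scaled.nodes[tib, 2], medial_template.nodes[tib, 2] * 0.5)
    v0 = kd.element_volumes(medial_template)
    v1 = kd.element_volumes(scaled)
    tib_e = medial_template.tissue == "tibial_cartilage"
    assert v1[tib_e].sum() / v0[tib_e].sum() == pytest.approx(0.5, rel=1e-12)
    # femoral thickness follows the (re-tilted) surface normals, so its
    # volume tracks the affine factor only approximately
    assert v1.sum() / v0.sum() == pytest.approx(0.5, rel=0.05)


def test_scaled_ratio_thickness_arithmetic(medial_template, template_measurements):
    """JS 4.79 mm at a 55% femoral fraction gives 2.6345 / 2.1555 mm."""
    scaled = scale_mesh(
        medial_template, template_measurements, template_measurements, "scaled_ratio"
    )
    assert scaled.thickness_femoral == pytest.approx(2.6345)
    assert scaled.thickness_tibial == pytest.approx(2.1555)


def test_fixed_ratio_volume_covariance(medial_template, template_measurements):
    """Tibial volume scales exactly with ap x ml x js ratios; the femoral
    cartilage (rescaled along curved normals) tracks within a few percent."""
    subject = dataclasses.replace(
        template_measurements,
        icd=template_measurements.icd * 1.15,
        ap_medial=template_measurements.ap_medial * 0.9,
        js_medial=template_measurements.js_medial * 1.2,
    )
    scaled = scale_mesh(medial_template, template_measurements, subject, "fixed_ratio")
    expected = 1.15 * 0.9 * 1.2
    v0 = kd.element_volumes(medial_template)
    v1 = kd.element_volumes(scaled)
    tib = medial_template.tissue == "tibial_cartilage"
    assert v1[tib].sum() / v0[tib].sum() == pytest.approx(expected, rel=1e-12)
    assert v1[~tib].sum() / v0[~tib].sum() == pytest.approx(expected, rel=0.05)


def test_scaling_preserves_topology_and_labels(
    medial_template, template_measurements
):
    subject = dataclasses.replace(template_measurements, icd=45.0, js_medial=4.0)
    scaled = scale_mesh(medial_template, template_measurements, subject, "scaled_ratio")
    assert np.array_equal(scaled.hexes, medial_template.hexes)
    assert np.array_equal(scaled.tissue, medial_template.tissue)
    assert np.array_equal(scaled.layer_index, medial_template.layer_index)
    assert scaled.n_elements == medial_template.n_elements
    assert corner_jacobians(scaled).min() > 0


def test_unknown_thickness_mode_rejected(medial_template, template_measurements):
    with pytest.raises(ValueError):
        scale_mesh(
            medial_template, template_measurements, template_measurements, "other"
        )


def _box_mesh(lx, ly, lz):
    nodes = np.array(
        [
            [0, 0, 0], [0, 0, lz], [lx, 0, lz], [lx, 0, 0],
            [0, ly, 0], [0, ly, lz], [lx, ly, lz], [lx, ly, 0],
        ],
        dtype=float,
    )
    return SimpleNamespace(nodes=nodes, hexes=np.array([[0, 1, 2, 3, 4, 5, 6, 7]]))


@pytest.mark.parametrize("dims,expected", [((1, 1, 1), 1.0), ((2, 1, 1), 2.0)])
def test_aspect_ratio_on_boxes(dims, expected):
    assert aspect_ratios(_box_mesh(*dims))[0] == pytest.approx(expected)


def test_mesh_quality_summary(medial_template):
    q = kd.mesh_quality(medial_template)
    assert q["min_jacobian"] > 0
    assert q["aspect_ratio_q1"] <= q["aspect_ratio_median"] <= q["aspect_ratio_q3"]
    assert q["mean_edge_length"] > 0


def test_region_partition_counts(medial_template):
    mesh = medial_template.copy()
    kd.partition_regions(mesh, central_fraction=1.0 - 1e-12)
    assert np.all(mesh.region == "central")

    kd.partition_regions(mesh, central_fraction=1.0 / 3.0)
    central = (mesh.region == "central").sum()
    per_slab = mesh.n_elements / mesh.nx
    assert abs(central - mesh.n_elements / 3) <= per_slab
    assert set(np.unique(mesh.region)) == {"anterior", "central", "posterior"}


def test_region_band_covariant_with_ap_scaling(
    medial_template, template_measurements
):
    subject = dataclasses.replace(
        template_measurements, ap_medial=template_measurements.ap_medial * 1.4
    )
    scaled = scale_mesh(medial_template, template_measurements, subject, "fixed_ratio")
    assert np.array_equal(scaled.region, medial_template.region)
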