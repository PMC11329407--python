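"""Layered hexahedral compartment templates and anatomy-driven mesh scaling.

A knee compartment (medial or lateral) is represented by two layered
hexahedral cartilage blocks: an ellipsoidal-cap femoral condyle surface above
a gently dished tibial plateau.  Axis convention:

* X — anterior(+)–posterior(−)
* Y — axial (loading direction, thickness)
* Z — medial–lateral

Subject-specific geometry is obtained by scaling a template: the A-P ratio
scales X, the intercondylar-distance ratio scales Z, and the joint-space (JS)
measurement rescales cartilage thickness — along Y for the tibial cartilage
and along per-column articular-surface normals ("radially") for the femoral
cartilage.  Two thickness modes are supported: ``fixed_ratio`` keeps the
template's femoral-to-tibial thickness ratio, ``scaled_ratio`` uses the
subject's measured femoral fraction of the joint space.  Both modes use the
same kinematic mechanism and coincide exactly when the subject's femoral
fraction equals the template's.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .cohort import AnatomicMeasurements

TEMPLATE_MEASUREMENTS = AnatomicMeasurements(
    icd=40.60,
    ap_medial=53.05,
    ap_lateral=62.59,
    js_medial=4.79,
    js_lateral=5.38,
    femoral_fraction_medial=0.55,
    femoral_fraction_lateral=0.40,
)


@dataclass(frozen=True)
class TemplateConfig:
    """Parametric template resolution and shape.

    Semi-axes describe the ellipsoidal femoral condyle cap (mm); the lateral
    compartment uses smaller semi-axes, i.e. a more curved (less congruent)
    femoral surface.  ``plate_ap_frac`` sets the modeled contact plate length
    as a fraction of the compartment A-P measurement.
    """

    nx: int = 16  # in-plane element divisions, anterior-posterior
    nz: int = 14  # in-plane element divisions, medial-lateral
    layers_femoral: int = 3
    layers_tibial: int = 3
    plate_ap_frac: float = 0.58
    ml_extent: float = 26.0  # mm
    condyle_semi_axes: dict = field(
        default_factory=lambda: {
            "medial": (36.0, 30.0, 24.0),  # (a_x, b_y, c_z) mm
            "lateral": (32.0, 24.0, 19.0),
        }
    )
    dish_depth: dict = field(
        default_factory=lambda: {"medial": 0.5, "lateral": 0.2}
    )
    apex_clearance: float = 0.05  # mm nominal separation at the condyle apex
    measurements: AnatomicMeasurements = TEMPLATE_MEASUREMENTS

    def __post_init__(self) -> None:
        if self.nx < 2 or self.nz < 2:
            raise ValueError("in-plane resolution must be at least 2x2")
        if self.layers_femoral < 3 or self.layers_tibial < 3:
            raise ValueError("each tissue needs at least 3 layers")


@dataclass
class CompartmentMesh:
    """Layered hexahedral mesh of one compartment (both cartilages).

    ``nodes`` are mm coordinates; ``hexes`` is 8-node connectivity in VTK
    hexahedron ordering.  Column metadata (per-node articular anchor, layer
    fraction and surface gradient) supports exact re-scaling and contact
    column construction.
    """

    nodes: np.ndarray  # (N, 3)
    hexes: np.ndarray  # (E, 8) int
    tissue: np.ndarray  # (E,) "femoral_cartilage" | "tibial_cartilage"
    region: np.ndarray  # (E,) "anterior" | "central" | "posterior"
    layer_index: np.ndarray  # (E,) int, 0 = articular surface layer
    compartment: str
    measurements: AnatomicMeasurements
    thickness_femoral: float
    thickness_tibial: float
    apex_clearance: float
    # structured metadata
    node_anchor: np.ndarray  # (N, 3) articular-surface anchor point
    node_s: np.ndarray  # (N,) layer fraction: 0 articular, 1 bone interface
    node_grad: np.ndarray  # (N, 2) articular surface (dy/dx, dy/dz) at anchor
    node_tissue: np.ndarray  # (N,) tissue label per node
    nx: int
    nz: int
    tib_surface_nodes: np.ndarray  # (nx+1, nz+1) node ids, tibial articular sheet
    fem_surface_nodes: np.ndarray  # (nx+1, nz+1) node ids, femoral articular sheet
    tib_col_elems: np.ndarray  # (nx, nz, layers_tibial) element ids
    fem_col_elems: np.ndarray  # (nx, nz, layers_femoral) element ids

    @property
    def n_elements(self) -> int:
        return len(self.hexes)

    def copy(self) -> "CompartmentMesh":
        return dataclasses.replace(
            self,
            nodes=self.nodes.copy(),
            region=self.region.copy(),
            node_anchor=self.node_anchor.copy(),
            node_grad=self.node_grad.copy(),
        )


# VTK hexahedron corner ordering used throughout: bottom face
# (i,k),(i,k+1),(i+1,k+1),(i+1,k), then the same on the upper sheet.
_TET_SPLIT = [
    (0, 1, 3, 4),
    (1, 2, 3, 6),
    (1, 3, 4, 6),
    (3, 4, 6, 7),
    (1, 4, 5, 6),
]


def element_volumes(mesh: CompartmentMesh) -> np.ndarray:
    """Signed hexahedron volumes via a 5-tetrahedron decomposition (mm^3)."""
    p = mesh.nodes[mesh.hexes]  # (E, 8, 3)
    vol = np.zeros(len(p))
    for a, b, c, d in _TET_SPLIT:
        e1 = p[:, b] - p[:, a]
        e2 = p[:, c] - p[:, a]
        e3 = p[:, d] - p[:, a]
        vol += np.einsum("ij,ij->i", np.cross(e1, e2), e3) / 6.0
    return vol


_EDGES = [
    (0, 1), (1, 2), (2, 3), (3, 0),
    (4, 5), (5, 6), (6, 7), (7, 4),
    (0, 4), (1, 5), (2, 6), (3, 7),
]

# (corner, +xi neighbour, +eta neighbour, +zeta neighbour) triads for the
# trilinear map; a valid hexahedron has positive determinant at every corner
_CORNER_TRIADS = [
    (0, 1, 3, 4), (1, 2, 0, 5), (2, 3, 1, 6), (3, 0, 2, 7),
    (4, 7, 5, 0), (5, 4, 6, 1), (6, 5, 7, 2), (7, 6, 4, 3),
]


def corner_jacobians(mesh: CompartmentMesh) -> np.ndarray:
    """Corner Jacobian determinants, (E, 8)."""
    p = mesh.nodes[mesh.hexes]
    out = np.empty((len(p), 8))
    for j, (c, a, b, d) in enumerate(_CORNER_TRIADS):
        e1 = p[:, a] - p[:, c]
        e2 = p[:, b] - p[:, c]
        e3 = p[:, d] - p[:, c]
        out[:, j] = np.einsum("ij,ij->i", np.cross(e1, e2), e3)
    return out


def aspect_ratios(mesh: CompartmentMesh) -> np.ndarray:
    """Longest/shortest edge length per hexahedron."""
    p = mesh.nodes[mesh.hexes]
    lengths = np.stack(
        [np.linalg.norm(p[:, b] - p[:, a], axis=1) for a, b in _EDGES], axis=1
    )
    return lengths.max(axis=1) / lengths.min(axis=1)


def mesh_quality(mesh: CompartmentMesh) -> dict:
    """Median/IQR aspect ratio, mean edge length (mm) and min corner Jacobian."""
    ar = aspect_ratios(mesh)
    p = mesh.nodes[mesh.hexes]
    lengths = np.concatenate(
        [np.linalg.norm(p[:, b] - p[:, a], axis=1) for a, b in _EDGES]
    )
    return {
        "aspect_ratio_median": float(np.median(ar)),
        "aspect_ratio_q1": float(np.percentile(ar, 25)),
        "aspect_ratio_q3": float(np.percentile(ar, 75)),
        "mean_edge_length": float(lengths.mean()),
        "min_jacobian": float(corner_jacobians(mesh).min()),
    }


def _condyle_surface(x, z, semi, y_apex):
    """Ellipsoidal-cap femoral articular surface height and gradient."""
    a, b, c = semi
    arg = 1.0 - (x / a) ** 2 - (z / c) ** 2
    arg = np.clip(arg, 0.02, None)  # keep the cap well-defined over the plate
    root = np.sqrt(arg)
    y = y_apex + b * (1.0 - root)
    gx = b * x / (a**2 * root)
    gz = b * z / (c**2 * root)
    return y, gx, gz


def build_template(
    compartment: str, config: TemplateConfig | None = None
) -> CompartmentMesh:
    """Build the parametric compartment template mesh.

    The femoral condyle is an ellipsoidal cap over a gently concave tibial
    plateau; both cartilages are uniform-thickness layered hexahedral grids.
    Template thicknesses come from the configured joint space and femoral
    fraction (JS = femoral + tibial cartilage thickness).
    """
    if compartment not in ("medial", "lateral"):
        raise ValueError(f"unknown compartment {compartment!r}")
    cfg = config or TemplateConfig()
    meas = cfg.measurements
    js = meas.joint_space(compartment)
    frac = meas.femoral_fraction(compartment)
    t_f = js * frac
    t_t = js * (1.0 - frac)

    ap = meas.ap_medial if compartment == "medial" else meas.ap_lateral
    ax = 0.5 * cfg.plate_ap_frac * ap
    az = 0.5 * cfg.ml_extent
    xs = np.linspace(-ax, ax, cfg.nx + 1)
    zs = np.linspace(-az, az, cfg.nz + 1)
    X, Z = np.meshgrid(xs, zs, indexing="ij")  # (nx+1, nz+1)

    dish = cfg.dish_depth[compartment]
    y_tt = dish * ((X / ax) ** 2 + (Z / az) ** 2)  # concave plateau, 0 at center
    g_tt_x = 2.0 * dish * X / ax**2
    g_tt_z = 2.0 * dish * Z / az**2

    semi = cfg.condyle_semi_axes[compartment]
    y_fa, g_fa_x, g_fa_z = _condyle_surface(X, Z, semi, cfg.apex_clearance)

    nx, nz = cfg.nx, cfg.nz
    Lf, Lt = cfg.layers_femoral, cfg.layers_tibial
    n_sheet = (nx + 1) * (nz + 1)

    nodes, anchors, svals, grads, ntis = [], [], [], [], []

    def add_block(y_surf, gx, gz, thickness, direction, layers, tissue):
        """direction +1: grow along +normal (femur); -1: straight down (tibia)."""
        anchor = np.stack([X, y_surf, Z], axis=-1).reshape(-1, 3)
        if direction > 0:
            n = np.stack([-gx, np.ones_like(gx), -gz], axis=-1).reshape(-1, 3)
            n /= np.linalg.norm(n, axis=1, keepdims=True)
        else:
            n = np.zeros((n_sheet, 3))
            n[:, 1] = -1.0
        sheet_ids = []
        for l in range(layers + 1):
            s = l / layers
            pos = anchor + s * thickness * n
            start = sum(len(a) for a in nodes)
            nodes.append(pos)
            anchors.append(anchor)
            svals.append(np.full(n_sheet, s))
            grads.append(np.stack([gx, gz], axis=-1).reshape(-1, 2))
            ntis.append(np.full(n_sheet, tissue, dtype="U17"))
            sheet_ids.append(start + np.arange(n_sheet))
        return sheet_ids

    # tibial block: sheets from articular surface (s=0) downward
    tib_sheets = add_block(y_tt, g_tt_x, g_tt_z, t_t, -1, Lt, "tibial_cartilage")
    # femoral block: sheets from articular surface (s=0) upward along normals
    fem_sheets = add_block(y_fa, g_fa_x, g_fa_z, t_f, +1, Lf, "femoral_cartilage")

    nodes = np.concatenate(nodes)
    node_anchor = np.concatenate(anchors)
    node_s = np.concatenate(svals)
    node_grad = np.concatenate(grads)
    node_tissue = np.concatenate(ntis)

    def sheet_grid(ids):
        return ids.reshape(nx + 1, nz + 1)

    hexes, tissue, layer_idx = [], [], []
    tib_col = np.zeros((nx, nz, Lt), dtype=int)
    fem_col = np.zeros((nx, nz, Lf), dtype=int)

    def add_cells(sheets, layers, tis, col, articular_first):
        # sheets[l] is at layer fraction l/layers from the articular surface;
        # build hexes between consecutive sheets with the LOWER-y sheet as the
        # bottom face so corner Jacobians are positive.
        for l in range(layers):
            lo = sheet_grid(sheets[l])
            hi = sheet_grid(sheets[l + 1])
            if articular_first:  # tibia: sheet l is ABOVE sheet l+1
                lo, hi = hi, lo
            for i in range(nx):
                for k in range(nz):
                    cell = [
                        lo[i, k], lo[i, k + 1], lo[i + 1, k + 1], lo[i + 1, k],
                        hi[i, k], hi[i, k + 1], hi[i + 1, k + 1], hi[i + 1, k],
                    ]
                    eid = len(hexes)
                    hexes.append(cell)
                    tissue.append(tis)
                    layer_idx.append(l)
                    col[i, k, l] = eid

    add_cells(tib_sheets, Lt, "tibial_cartilage", tib_col, articular_first=True)
    add_cells(fem_sheets, Lf, "femoral_cartilage", fem_col, articular_first=False)

    mesh = CompartmentMesh(
        nodes=nodes,
        hexes=np.asarray(hexes, dtype=int),
        tissue=np.asarray(tissue, dtype="U17"),
        region=np.full(len(hexes), "unassigned", dtype="U10"),
        layer_index=np.asarray(layer_idx, dtype=int),
        compartment=compartment,
        measurements=meas,
        thickness_femoral=t_f,
        thickness_tibial=t_t,
        apex_clearance=cfg.apex_clearance,
        node_anchor=node_anchor,
        node_s=node_s,
        node_grad=node_grad,
        node_tissue=node_tissue,
        nx=nx,
        nz=nz,
        tib_surface_nodes=sheet_grid(tib_sheets[0]),
        fem_surface_nodes=sheet_grid(fem_sheets[0]),
        tib_col_elems=tib_col,
        fem_col_elems=fem_col,
    )
    partition_regions(mesh)
    if corner_jacobians(mesh).min() <= 0:
        raise ValueError("degenerate template resolution: non-positive Jacobian")
    return mesh


def partition_regions(
    mesh: CompartmentMesh, central_fraction: float = 1.0 / 3.0
) -> CompartmentMesh:
    """Label elements anterior/central/posterior by centroid X position.

    The central band covers ``central_fraction`` of the tibial plateau's A-P
    extent, centered; anterior is +X.  Mutates and returns the mesh.
    """
    if not 0.0 < central_fraction <= 1.0:
        raise ValueError("central_fraction must lie in (0, 1]")
    tib_nodes = mesh.nodes[mesh.node_tissue == "tibial_cartilage"]
    x_min, x_max = tib_nodes[:, 0].min(), tib_nodes[:, 0].max()
    span = x_max - x_min
    lo = x_min + 0.5 * (1.0 - central_fraction) * span
    hi = x_max - 0.5 * (1.0 - central_fraction) * span
    cx = mesh.nodes[mesh.hexes][:, :, 0].mean(axis=1)
    region = np.full(mesh.n_elements, "central", dtype="U10")
    region[cx > hi] = "anterior"
    region[cx < lo] = "posterior"
    mesh.region = region
    return mesh


def scale_mesh(
    template: CompartmentMesh,
    template_meas: AnatomicMeasurements,
    subject_meas: AnatomicMeasurements,
    mode: str = "fixed_ratio",
    central_fraction: float = 1.0 / 3.0,
) -> CompartmentMesh:
    """Scale the template to a subject's anatomy.

    X scales by the compartment A-P ratio, Z by the ICD ratio.  Thickness:
    ``fixed_ratio`` multiplies both cartilage thicknesses by the JS ratio
    (template femoral fraction preserved); ``scaled_ratio`` sets femoral
    thickness = JS x femoral fraction and tibial = JS x (1 - fraction) from
    the subject's measurements.  Tibial thickness changes act along Y about
    the articular surface; femoral thickness changes act along the (scaled)
    per-column articular-surface normals.  The femoral body is then
    repositioned vertically to restore the template's apex clearance.
    """
    if mode not in ("fixed_ratio", "scaled_ratio"):
        raise ValueError(f"unknown thickness mode {mode!r}")
    comp = template.compartment
    ap_t = template_meas.ap_medial if comp == "medial" else template_meas.ap_lateral
    ap_s = subject_meas.ap_medial if comp == "medial" else subject_meas.ap_lateral
    ap_ratio = ap_s / ap_t
    ml_ratio = subject_meas.icd / template_meas.icd
    js_s = subject_meas.joint_space(comp)

    if mode == "fixed_ratio":
        frac = template_meas.femoral_fraction(comp)  # template ratio preserved
    else:
        frac = subject_meas.femoral_fraction(comp)
    t_f = js_s * frac
    t_t = js_s * (1.0 - frac)
    if t_f <= 0 or t_t <= 0:
        raise ValueError("scaling produced a non-positive cartilage thickness")

    mesh = template.copy()
    anchor = mesh.node_anchor
    anchor[:, 0] *= ap_ratio
    anchor[:, 2] *= ml_ratio
    grad = mesh.node_grad
    grad[:, 0] /= ap_ratio
    grad[:, 1] /= ml_ratio

    fem = mesh.node_tissue == "femoral_cartilage"
    tib = ~fem
    s = mesh.node_s
    # tibia: straight down along Y from the articular anchor
    mesh.nodes[tib] = anchor[tib]
    mesh.nodes[tib, 1] -= s[tib] * t_t
    # femur: along the scaled articular-surface normal
    n = np.empty((fem.sum(), 3))
    n[:, 0] = -grad[fem, 0]
    n[:, 1] = 1.0
    n[:, 2] = -grad[fem, 1]
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    mesh.nodes[fem] = anchor[fem] + (s[fem] * t_f)[:, None] * n

    # restore the nominal apex clearance between the articular surfaces
    fem_y = mesh.nodes[mesh.fem_surface_nodes.ravel(), 1]
    tib_y = mesh.nodes[mesh.tib_surface_nodes.ravel(), 1]
    shift = template.apex_clearance - (fem_y - tib_y).min()
    mesh.nodes[fem, 1] += shift
    anchor[fem, 1] += shift

    mesh.measurements = subject_meas
    mesh.thickness_femoral = t_f
    mesh.thickness_tibial = t_t
    partition_regions(mesh, central_fraction)
    return mesh
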