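"""Maximum-principal solid-stress fields from an elastic-foundation contact
surrogate for fibril-reinforced cartilage.

The full biphasic fibril-reinforced finite-element solve is replaced by an
instantaneous-incompressible column model: over the ~1 s of a stance phase
fluid exchange is negligible, so the cartilage responds as an incompressible
solid whose compressive stiffness is dominated by in-plane stretching of the
tension-only collagen network.  The contact interface is discretized into
independent vertical columns (elastic-foundation approximation); at each
stance frame a rigid axial approach of the femur is found so that the summed
column pressures balance the applied compartmental joint contact force.

Closed form per tissue sub-column at compressive engineering strain e:

    axial stretch       lam  = 1 - e
    in-plane stretch    lamt = lam^(-1/2)          (isochoric)
    fibril strain       E_f  = (lamt^2 - 1)/2      (Green-Lagrange)
    fibril stresses     s_p  = xi_fp E_f^beta_fp,  s_s = xi_fs E_f^beta_fs
    matrix shear        mu   = E_nf / (2 (1 + nu_nf))
    matrix deviatoric   s_m  = mu (lamt^2 - lam^2)
    surface stress      sigma_I = s_p + s_s + s_m
    column pressure     p    = mu (lam^-1 - lam^2) + s_p + s_s

(The incompressible kinematics make lam^-1 = lamt^2, so the column pressure
coincides with the surface maximum principal stress.)  The femoral and
tibial sub-columns act in series: the total strain is partitioned so their
pressures match.  Per-element stresses are the column surface value scaled
by a depth-weight profile standing in for the arcade-like depth variation of
collagen orientation (superficial 1.0, middle 0.5, deep 0.25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lxml import etree
from scipy.interpolate import PchipInterpolator

from .geometry import CompartmentMesh, element_volumes
from .loading import GaitLoading

STRAIN_CAP = 0.6
_EPS_MAX_TISSUE = 0.97  # tissue sub-column strains stay below this internally

DEPTH_WEIGHTS = ((0.0, 1.0), (0.5, 0.5), (1.0, 0.25))


@dataclass(frozen=True)
class MaterialProps:
    """Fibril-reinforced biphasic cartilage constants.

    ``kappa0`` (initial permeability, 1e-15 m^4 N^-1 s^-1), ``M_perm``
    (strain-dependent permeability exponent) and ``phi0`` (initial solid
    fraction) are carried for solver-deck export; the instantaneous surrogate
    involves no fluid flow and does not use them.
    """

    xi_fp: float  # MPa, primary-fibril stiffness
    beta_fp: float
    xi_fs: float  # MPa, secondary-fibril stiffness
    beta_fs: float
    E_nf: float  # MPa, non-fibrillar matrix Young's modulus
    nu_nf: float
    kappa0: float
    M_perm: float
    phi0: float
    tissue: str


TIBIA_PROPS = MaterialProps(32.0, 2.6, 1.0, 2.6, 0.106, 0.15, 18.0, 15.24, 0.2, "tibia")
FEMUR_PROPS = MaterialProps(215.0, 2.6, 3.0, 2.6, 0.215, 0.15, 6.0, 5.06, 0.2, "femur")


def tissue_stress(eps, props: MaterialProps):
    """(pressure, sigma_I) of one tissue sub-column at compressive strain eps."""
    eps = np.clip(np.asarray(eps, dtype=float), 0.0, _EPS_MAX_TISSUE)
    lam = 1.0 - eps
    lamt2 = 1.0 / lam
    E_f = 0.5 * (lamt2 - 1.0)
    if props.beta_fp == props.beta_fs:
        s_fib = (props.xi_fp + props.xi_fs) * E_f**props.beta_fp
    else:
        s_fib = props.xi_fp * E_f**props.beta_fp + props.xi_fs * E_f**props.beta_fs
    mu = props.E_nf / (2.0 * (1.0 + props.nu_nf))
    s_m = mu * (lamt2 - lam**2)
    sigma = s_fib + s_m
    pressure = mu * (1.0 / lam - lam**2) + s_fib
    return pressure, sigma


@dataclass
class ColumnResponse:
    pressure: float
    sigma_femoral: float
    sigma_tibial: float
    eps_femoral: float
    eps_tibial: float
    capped: bool = False


class ColumnLaw:
    """Series femur/tibia column response for a given thickness split.

    ``rho`` is the femoral fraction of the total column thickness.  The
    strain partition (pressure matching) is solved by vectorized bisection;
    a monotone cubic interpolant of p(eps_total) provides a fast path for
    the equilibrium root-find, which is always polished against the exact
    law.
    """

    _EPS_GRID_MAX = 0.75

    def __init__(self, props_f: MaterialProps, props_t: MaterialProps, rho: float):
        if not 0.0 < rho < 1.0:
            raise ValueError("femoral thickness fraction must lie in (0, 1)")
        self.props_f = props_f
        self.props_t = props_t
        self.rho = rho
        self._split_spline = None
        self._p_spline = None

    def partition(self, eps_total):
        """Split total strain into (eps_f, eps_t) with matched pressures
        (bisection to machine precision)."""
        eps_total = np.asarray(eps_total, dtype=float)
        rho = self.rho
        lo = np.maximum(0.0, (eps_total - _EPS_MAX_TISSUE * (1.0 - rho)) / rho)
        hi = np.minimum(eps_total / rho, _EPS_MAX_TISSUE)
        for _ in range(55):
            mid = 0.5 * (lo + hi)
            eps_t = (eps_total - rho * mid) / (1.0 - rho)
            g = tissue_stress(mid, self.props_f)[0] - tissue_stress(eps_t, self.props_t)[0]
            lo = np.where(g < 0, mid, lo)
            hi = np.where(g < 0, hi, mid)
        eps_f = 0.5 * (lo + hi)
        eps_t = (eps_total - rho * eps_f) / (1.0 - rho)
        return eps_f, np.clip(eps_t, 0.0, _EPS_MAX_TISSUE)

    def _build_splines(self) -> None:
        grid = np.linspace(0.0, self._EPS_GRID_MAX, 3001)
        eps_f, _ = self.partition(grid)
        self._split_spline = PchipInterpolator(grid, eps_f)
        self._p_spline = PchipInterpolator(grid, tissue_stress(eps_f, self.props_f)[0])

    def pressure(self, eps_total):
        """Matched-pressure column response: the femoral sub-column strain is
        taken from a dense monotone-cubic interpolant of the bisection
        partition (interpolation error far below solver tolerances) and the
        pressure evaluated through the exact tissue law."""
        if self._split_spline is None:
            self._build_splines()
        eps_total = np.clip(eps_total, 0.0, self._EPS_GRID_MAX)
        return tissue_stress(self._split_spline(eps_total), self.props_f)[0]

    def pressure_fast(self, eps_total):
        """Directly interpolated column pressure (used to bracket roots)."""
        if self._p_spline is None:
            self._build_splines()
        return self._p_spline(np.clip(eps_total, 0.0, self._EPS_GRID_MAX))


def column_response(
    epsilon: float,
    props_f: MaterialProps = FEMUR_PROPS,
    props_t: MaterialProps = TIBIA_PROPS,
    thickness_f: float = 1.0,
    thickness_t: float = 1.0,
) -> ColumnResponse:
    """Series column response at total compressive strain ``epsilon``."""
    if epsilon < 0:
        raise ValueError("compressive strain must be non-negative")
    capped = False
    if epsilon >= STRAIN_CAP:
        warnings.warn("column strain at cap: response saturates", stacklevel=2)
        epsilon = STRAIN_CAP
        capped = True
    law = ColumnLaw(props_f, props_t, thickness_f / (thickness_f + thickness_t))
    eps_f, eps_t = law.partition(epsilon)
    p = float(tissue_stress(eps_f, props_f)[0])
    return ColumnResponse(
        pressure=p,
        sigma_femoral=float(tissue_stress(eps_f, props_f)[1]),
        sigma_tibial=float(tissue_stress(eps_t, props_t)[1]),
        eps_femoral=float(eps_f),
        eps_tibial=float(eps_t),
        capped=capped,
    )


@dataclass
class ContactColumns:
    """Contact interface discretization for one flexion angle."""

    gap: np.ndarray  # (nc,) signed vertical gap, mm; +inf = non-contacting
    area: np.ndarray  # (nc,) projected facet area, mm^2
    thickness_f: float
    thickness_t: float
    fem_pair: np.ndarray  # (nc,) paired femoral column id (flattened i*nz+k)
    flexion_deg: float

    @property
    def total_thickness(self) -> float:
        return self.thickness_f + self.thickness_t


def _facet_geometry(mesh: CompartmentMesh):
    """Tibial articular facet centroids and projected XZ areas."""
    tib_pts = mesh.nodes[mesh.tib_surface_nodes]  # (nx+1, nz+1, 3)
    c00 = tib_pts[:-1, :-1]
    c01 = tib_pts[:-1, 1:]
    c11 = tib_pts[1:, 1:]
    c10 = tib_pts[1:, :-1]
    cen = 0.25 * (c00 + c01 + c11 + c10)  # (nx, nz, 3)
    x0, z0 = c00[..., 0], c00[..., 2]
    x1, z1 = c01[..., 0], c01[..., 2]
    x2, z2 = c11[..., 0], c11[..., 2]
    x3, z3 = c10[..., 0], c10[..., 2]
    area = 0.5 * np.abs(
        x0 * z1 - x1 * z0 + x1 * z2 - x2 * z1 + x2 * z3 - x3 * z2 + x3 * z0 - x0 * z3
    )
    return cen, area


def _gap_matrices(mesh: CompartmentMesh, angles):
    """Vectorized vertical gaps for a set of flexion angles.

    The femoral articular surface is rotated about the Z axis through the
    condyle-surface centroid; positive flexion migrates the contact point
    posteriorly (-X).  Z is unchanged by the rotation, so the rotated
    surface is interpolated in X along each mediolateral node row and
    averaged between the two rows bracketing each tibial facet.

    Returns gap (F, nc), fem_pair (F, nc), area (nc,).
    """
    nx, nz = mesh.nx, mesh.nz
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    fem_pts = mesh.nodes[mesh.fem_surface_nodes]  # (nx+1, nz+1, 3)
    cx, cy = fem_pts[..., 0].mean(), fem_pts[..., 1].mean()
    th = np.deg2rad(angles)[:, None, None]
    dx = fem_pts[None, ..., 0] - cx
    dy = fem_pts[None, ..., 1] - cy
    fx = cx + dx * np.cos(th) - dy * np.sin(th)  # (F, nx+1, nz+1)
    fy = cy + dx * np.sin(th) + dy * np.cos(th)

    cen, area = _facet_geometry(mesh)
    xq = cen[:, 0, 0]  # facet centroid X, shared across rows of the grid

    # bracketing interval per (frame, query, node-row): rotated x stays
    # monotone in i for the flexion range of gait
    idx = (xq[None, :, None, None] >= fx[:, None, :, :]).sum(axis=2) - 1
    idx = np.clip(idx, 0, nx - 1)  # (F, nx, nz+1)
    f_idx = np.arange(len(angles))[:, None, None]
    r_idx = np.arange(nz + 1)[None, None, :]
    x_lo = fx[f_idx, idx, r_idx]
    x_hi = fx[f_idx, idx + 1, r_idx]
    y_lo = fy[f_idx, idx, r_idx]
    y_hi = fy[f_idx, idx + 1, r_idx]
    t = (xq[None, :, None] - x_lo) / (x_hi - x_lo)
    y = y_lo + t * (y_hi - y_lo)
    outside = (xq[None, :, None] < fx[:, 0:1, :]) | (xq[None, :, None] > fx[:, -1:, :])
    y = np.where(outside, np.inf, y)

    y_f = 0.5 * (y[:, :, :-1] + y[:, :, 1:])  # (F, nx, nz)
    gap = y_f - cen[None, :, :, 1]
    fem_pair = idx[:, :, :-1] * nz + np.arange(nz)[None, None, :]
    return gap.reshape(len(angles), -1), fem_pair.reshape(len(angles), -1), area.ravel()


def build_columns(mesh: CompartmentMesh, flexion_angle: float) -> ContactColumns:
    """Discretize the contact interface at one flexion angle."""
    gap, fem_pair, area = _gap_matrices(mesh, [flexion_angle])
    return ContactColumns(
        gap=gap[0],
        area=area,
        thickness_f=mesh.thickness_femoral,
        thickness_t=mesh.thickness_tibial,
        fem_pair=fem_pair[0],
        flexion_deg=float(flexion_angle),
    )


@dataclass
class FrameSolution:
    delta: float
    pressure: np.ndarray  # (nc,) MPa
    contact_area: float  # mm^2
    residual: float  # |sum(pA) - F| / max(F, 1)


@dataclass
class StressField:
    """Per-element maximum principal solid stress over the stance phase."""

    sigma_history: np.ndarray  # (n_frames, E) MPa
    envelope: np.ndarray  # (E,) max over frames
    contact_area: np.ndarray  # (n_frames,) mm^2
    residual: np.ndarray  # (n_frames,) relative equilibrium residual
    pressure_max: np.ndarray  # (n_frames,) peak column pressure
    compartment: str = ""
    scheme: str = ""


def _depth_weight(layer_frac: np.ndarray) -> np.ndarray:
    xs = [p[0] for p in DEPTH_WEIGHTS]
    ys = [p[1] for p in DEPTH_WEIGHTS]
    return np.interp(layer_frac, xs, ys)


def solve_contact_frame(
    columns: ContactColumns,
    force: float,
    law: ColumnLaw | None = None,
    props_f: MaterialProps = FEMUR_PROPS,
    props_t: MaterialProps = TIBIA_PROPS,
) -> FrameSolution:
    """Find the rigid axial approach balancing one frame's applied force."""
    if force < 0:
        raise ValueError("applied force must be non-negative")
    if law is None:
        law = ColumnLaw(props_f, props_t, columns.thickness_f / columns.total_thickness)
    gap = columns.gap[None, :]
    area = columns.area[None, :]
    delta, pressure, residual = _solve_frames(
        law, gap, area, np.array([force]), columns.total_thickness, label="frame"
    )
    p = pressure[0]
    return FrameSolution(
        delta=float(delta[0]),
        pressure=p,
        contact_area=float(columns.area[p > 0].sum()),
        residual=float(residual[0]),
    )


def _solve_frames(law, gap, area, forces, T, label="stance"):
    """Vectorized equilibrium solve across frames.

    gap: (F, nc); area: (1 or F, nc); forces: (F,).  Returns delta (F,),
    pressure (F, nc), residual (F,).
    """
    nf = len(forces)
    finite = np.isfinite(gap)
    min_gap = np.where(finite, gap, np.inf).min(axis=1)
    delta_cap = min_gap + STRAIN_CAP * T
    # the femur may lift off (delta below the smallest gap) to balance
    # near-zero forces when flexion rotation creates slight interference
    delta_lo = np.minimum(min_gap, 0.0)

    def eps_of(delta):
        e = (delta[:, None] - gap) / T
        return np.clip(np.where(finite, e, 0.0), 0.0, None)

    f_cap = (law.pressure(eps_of(delta_cap)) * area).sum(axis=1)
    over = forces > f_cap * (1.0 + 1e-9)
    if np.any(over):
        i = int(np.argmax(over))
        raise ValueError(
            f"{label} {i}: applied force {forces[i]:.1f} N exceeds column "
            f"capacity {f_cap[i]:.1f} N at the strain cap"
        )

    lo = delta_lo.copy()
    hi = delta_cap.copy()
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        f_mid = (law.pressure_fast(eps_of(mid)) * area).sum(axis=1)
        lo = np.where(f_mid < forces, mid, lo)
        hi = np.where(f_mid < forces, hi, mid)
    delta = 0.5 * (lo + hi)

    # polish against the constitutive evaluation (Newton on summed pressures)
    for _ in range(4):
        eps = eps_of(delta)
        pressure = law.pressure(eps)
        f_now = (pressure * area).sum(axis=1)
        resid = f_now - forces
        rel = np.abs(resid) / np.maximum(forces, 1.0)
        if rel.max() < 1e-9:
            break
        h = 1e-7 * T
        f_up = (law.pressure(eps_of(delta + h)) * area).sum(axis=1)
        slope = np.maximum((f_up - f_now) / h, 1e-12)
        step = np.where(rel > 1e-9, resid / slope, 0.0)
        delta = np.clip(delta - step, delta_lo, delta_cap)
    eps = eps_of(delta)
    pressure = law.pressure(eps)
    pressure[eps <= 0] = 0.0
    resid = np.abs((pressure * area).sum(axis=1) - forces) / np.maximum(forces, 1.0)
    return delta, pressure, resid


def simulate_stance(
    mesh: CompartmentMesh,
    loading: GaitLoading,
    props_f: MaterialProps = FEMUR_PROPS,
    props_t: MaterialProps = TIBIA_PROPS,
) -> StressField:
    """Solve every stance frame and assemble the per-element stress field.

    Per frame, the compartment force is balanced at the frame's flexion
    angle; per-element sigma_I is the column surface stress scaled by the
    depth-weight profile, assigned to the tibial column and its paired
    femoral column.  The envelope (max over frames) feeds the degeneration
    criterion.
    """
    forces = loading.force(mesh.compartment)
    angles = loading.flexion_deg
    nf = len(forces)
    law = ColumnLaw(props_f, props_t, mesh.thickness_femoral / (mesh.thickness_femoral + mesh.thickness_tibial))

    gap, fem_pair, area = _gap_matrices(mesh, angles)
    T = mesh.thickness_femoral + mesh.thickness_tibial

    delta, pressure, residual = _solve_frames(law, gap, area[None, :], forces, T)

    lt = mesh.tib_col_elems.shape[2]
    lf = mesh.fem_col_elems.shape[2]
    w_t = _depth_weight(np.arange(lt) / max(lt - 1, 1))
    w_f = _depth_weight(np.arange(lf) / max(lf - 1, 1))
    tib_elems = mesh.tib_col_elems.reshape(-1, lt)  # (nc, lt)
    fem_elems = mesh.fem_col_elems.reshape(-1, lf)

    sigma = np.zeros((nf, mesh.n_elements))
    for f in range(nf):
        p = pressure[f]
        sigma[f, tib_elems] = p[:, None] * w_t[None, :]
        fem_p = np.zeros(fem_elems.shape[0])
        np.maximum.at(fem_p, fem_pair[f], p)
        sigma[f, fem_elems] = fem_p[:, None] * w_f[None, :]

    contact_area = ((pressure > 0) * area[None, :]).sum(axis=1)
    return StressField(
        sigma_history=sigma,
        envelope=sigma.max(axis=0),
        contact_area=contact_area,
        residual=residual,
        pressure_max=pressure.max(axis=1),
        compartment=mesh.compartment,
        scheme=loading.scheme,
    )


def export_solver_deck(
    mesh: CompartmentMesh,
    loading: GaitLoading,
    path,
    props_f: MaterialProps = FEMUR_PROPS,
    props_t: MaterialProps = TIBIA_PROPS,
) -> None:
    """Write an XML solver deck (FEBio-format dialect) for full-fidelity runs.

    Carries the complete biphasic fibril-reinforced constants (including the
    permeability parameters unused by the instantaneous surrogate), the
    hexahedral mesh, tibial base fixation, and the stance force/flexion
    curves.
    """
    root = etree.Element("febio_spec", version="3.0")
    etree.SubElement(root, "Module", type="biphasic")

    materials = etree.SubElement(root, "Material")
    for mid, props, name in (
        (1, props_f, "femoral_cartilage"),
        (2, props_t, "tibial_cartilage"),
    ):
        mat = etree.SubElement(
            materials, "material", id=str(mid), name=name, type="biphasic-fibril-reinforced"
        )
        for tag, value in (
            ("xi_fp", props.xi_fp),
            ("beta_fp", props.beta_fp),
            ("xi_fs", props.xi_fs),
            ("beta_fs", props.beta_fs),
            ("E_nf", props.E_nf),
            ("nu_nf", props.nu_nf),
            ("phi0", props.phi0),
        ):
            etree.SubElement(mat, tag).text = repr(float(value))
        perm = etree.SubElement(mat, "permeability", type="perm-Holmes-Mow")
        etree.SubElement(perm, "perm").text = repr(float(props.kappa0))
        etree.SubElement(perm, "M").text = repr(float(props.M_perm))

    geom = etree.SubElement(root, "Mesh")
    nodes_el = etree.SubElement(geom, "Nodes", name=f"{mesh.compartment}_compartment")
    for i, p in enumerate(mesh.nodes, start=1):
        etree.SubElement(nodes_el, "node", id=str(i)).text = ",".join(
            repr(float(v)) for v in p
        )
    for tissue, mid in (("femoral_cartilage", 1), ("tibial_cartilage", 2)):
        sel = np.flatnonzero(mesh.tissue == tissue)
        elems = etree.SubElement(
            geom, "Elements", type="hex8", name=tissue, mat=str(mid)
        )
        for eid in sel:
            conn = mesh.hexes[eid] + 1
            etree.SubElement(elems, "elem", id=str(int(eid) + 1)).text = ",".join(
                str(int(v)) for v in conn
            )

    boundary = etree.SubElement(root, "Boundary")
    tib_base = np.flatnonzero(
        (mesh.node_tissue == "tibial_cartilage") & (mesh.node_s >= 1.0 - 1e-12)
    )
    fix = etree.SubElement(boundary, "bc", type="fix", node_set="tibial_base")
    etree.SubElement(fix, "dofs").text = "x,y,z"
    ns = etree.SubElement(boundary, "NodeSet", name="tibial_base")
    for nid in tib_base:
        etree.SubElement(ns, "n", id=str(int(nid) + 1))

    loads = etree.SubElement(root, "LoadData")
    for cid, name, values in (
        (1, "axial_force", loading.force(mesh.compartment)),
        (2, "flexion_angle", loading.flexion_deg),
    ):
        lc = etree.SubElement(
            loads, "load_controller", id=str(cid), name=name, type="loadcurve"
        )
        pts = etree.SubElement(lc, "points")
        for s, v in zip(loading.stance_percent, values):
            etree.SubElement(pts, "point").text = f"{s!r},{float(v)!r}"

    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")
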