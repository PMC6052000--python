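"""Axisymmetric finite-element simulation of a contracting cell in a fibrous matrix.

A single cell is modeled as an ellipsoidal cavity (axisymmetric about the
tendon/loading axis, mirror-symmetric about its equatorial midplane) embedded
in a matrix governed by the fibrous constitutive law.  The cavity surface is
pulled inward to emulate active cytoskeletal contraction (default 5% volume
loss) and the quasi-static finite-deformation equilibrium is solved on the
quarter (r, z) half-plane with 3-node axisymmetric triangles (one-point
quadrature, total-Lagrangian Newton iterations).

The displacement magnitude decays with distance from the cell approximately
as a power law u(r) ~ r^-eta.  In a linear isotropic matrix eta -> 2 (the
classical spherical-cavity solution); fibrous strain stiffening lowers eta,
i.e. transmits displacement much farther — the mechanism by which cells in
aligned tissue sense each other over many cell radii.  A 1-D spherically
symmetric reduced solver under the same law ships as an independent check
for spherical cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import sparse
from scipy.interpolate import LinearNDInterpolator
from scipy.sparse.linalg import spsolve

from .constitutive import FibrousMatrixParams, cauchy_stress_batch


class Polarization(str, Enum):
    isotropic = "isotropic"
    axial = "axial"


@dataclass(frozen=True)
class CellGeometry:
    """Contracting cell: equivalent radius (µm), shape, and contraction mode.

    ``aspect_ratio`` is major/minor of the axisymmetric ellipsoid (major axis
    along z, the tendon axis); 1 is a sphere (rounded cell), >1 a spindle.
    ``contraction_volume_fraction`` is the fraction of cell volume lost
    (default 0.05, i.e. the cell contracts to 95% of its original volume).
    """

    a: float = 5.0
    aspect_ratio: float = 1.0
    contraction_volume_fraction: float = 0.05
    polarization: Polarization = Polarization.isotropic

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("equivalent radius must be > 0")
        if self.aspect_ratio < 1:
            raise ValueError("aspect ratio must be >= 1")
        if not 0 < self.contraction_volume_fraction < 1:
            raise ValueError("contraction volume fraction must lie in (0, 1)")

    @property
    def semi_axis_z(self) -> float:
        """Major (axial) semi-axis, µm (equal-volume ellipsoid)."""
        return self.a * self.aspect_ratio ** (2.0 / 3.0)

    @property
    def semi_axis_r(self) -> float:
        """Minor (radial) semi-axis, µm."""
        return self.a / self.aspect_ratio ** (1.0 / 3.0)


@dataclass(frozen=True)
class MeshSpec:
    """Graded mesh sizing: element size near the cell -> far field (µm)."""

    near_size: float = 1.0
    far_size: float = 6.0
    R_out: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.near_size <= self.far_size < self.R_out):
            raise ValueError("require 0 < near_size <= far_size < R_out")

    def refined(self, factor: float = 2.0) -> "MeshSpec":
        return MeshSpec(self.near_size / factor, self.far_size / factor, self.R_out)


@dataclass
class Mesh:
    """Quarter-domain triangulation: nodes (r, z), triangles, boundary sets."""

    nodes: np.ndarray          # (N, 2) reference coordinates (r, z), µm
    triangles: np.ndarray      # (M, 3) node indices, counterclockwise
    cavity_nodes: np.ndarray   # indices on the cell surface
    outer_nodes: np.ndarray    # indices on r^2+z^2 = R_out^2
    axis_nodes: np.ndarray     # indices on r = 0 (excluding cavity/outer)
    midplane_nodes: np.ndarray # indices on z = 0 (excluding cavity/outer)
    min_angle_deg: float = 0.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class DisplacementField:
    mesh: Mesh
    u: np.ndarray              # (N, 2) displacements (u_r, u_z), µm
    cell: CellGeometry
    params: FibrousMatrixParams


@dataclass
class DisplacementProfile:
    """|u| sampled along rays emanating from the cell surface.

    ``r`` is distance from the cell perimeter; ``r_center`` from the cell
    center (the coordinate in which the power-law decay is fitted).
    """

    r: np.ndarray
    r_center: np.ndarray
    u: np.ndarray
    ray_angles_deg: np.ndarray
    per_ray_u: np.ndarray      # (n_rays, n_samples), NaN where outside domain
    a: float
    R_out: float
    truncated: bool = False


@dataclass
class DecayFit:
    eta: float
    prefactor: float
    r_range: tuple[float, float]
    r_squared: float
    n_points: int
    eta_eff: float | None = None


# ---------------------------------------------------------------------------
# meshing

def _radial_layers(near: float, far: float, length: float) -> np.ndarray:
    """Geometric layer thicknesses growing near -> far, rescaled to ``length``."""
    if far <= near * (1 + 1e-12):
        n = max(int(np.ceil(length / near)), 1)
        return np.full(n, length / n)
    for n in range(2, 10000):
        g = (far / near) ** (1.0 / (n - 1))
        total = near * (g ** n - 1.0) / (g - 1.0)
        if total >= length:
            t = near * g ** np.arange(n)
            return t * (length / total)
    raise RuntimeError("mesh grading failed")


def build_mesh(cell: CellGeometry, spec: MeshSpec | None = None) -> Mesh:
    """Structured graded mesh of the quarter domain outside the cell cavity.

    Rays fan from the elliptical cavity surface to the outer quarter-circle;
    layer thickness grows geometrically from ``near_size`` at the cell to
    ``far_size`` at ``R_out``.  Quads are split along alternating diagonals.
    """
    spec = spec or MeshSpec()
    br, bz = cell.semi_axis_r, cell.semi_axis_z
    if bz >= spec.R_out or br >= spec.R_out:
        raise ValueError("cell does not fit inside the domain")

    # angular count: bounded cavity-surface spacing (largest ~ bz * dt at the
    # equator of the parameterization) and bounded far-field aspect ratio
    n_near = max(bz, br) * (np.pi / 2.0) / spec.near_size
    n_far = (np.pi / 2.0) * spec.R_out / (2.5 * spec.far_size)
    n_theta = max(6, int(np.ceil(max(n_near, n_far))))
    t = np.linspace(0.0, np.pi / 2.0, n_theta + 1)  # 0 = midplane, pi/2 = axis

    # transfinite blend between the cavity ellipse (parameter t) and the
    # outer quarter circle at the same parameter
    ct, st = np.cos(t), np.sin(t)
    cav_r, cav_z = br * ct, bz * st
    out_r, out_z = spec.R_out * ct, spec.R_out * st
    ray_len = np.hypot(out_r - cav_r, out_z - cav_z)

    layers = _radial_layers(spec.near_size, spec.far_size, ray_len.min())
    n_rad = len(layers)
    frac = np.concatenate([[0.0], np.cumsum(layers)]) / layers.sum()  # 0..1

    # node grid: (n_rad+1, n_theta+1)
    R = cav_r[None, :] + frac[:, None] * (out_r - cav_r)[None, :]
    Z = cav_z[None, :] + frac[:, None] * (out_z - cav_z)[None, :]
    nid = np.arange((n_rad + 1) * (n_theta + 1)).reshape(n_rad + 1, n_theta + 1)

    # Laplacian smoothing of interior grid nodes relieves skew where rays
    # meet the cavity ellipse obliquely; boundary rows/columns stay fixed
    for _ in range(4):
        interior = 0.25 * (R[:-2, 1:-1] + R[2:, 1:-1] + R[1:-1, :-2]
                           + R[1:-1, 2:])
        R[1:-1, 1:-1] = interior
        interior_z = 0.25 * (Z[:-2, 1:-1] + Z[2:, 1:-1] + Z[1:-1, :-2]
                             + Z[1:-1, 2:])
        Z[1:-1, 1:-1] = interior_z

    nodes = np.stack([R.ravel(), Z.ravel()], axis=1)
    nodes[np.abs(nodes) < 1e-12] = 0.0  # snap symmetry boundaries exactly

    tris = []
    for i in range(n_rad):
        for j in range(n_theta):
            n00, n01 = nid[i, j], nid[i, j + 1]
            n10, n11 = nid[i + 1, j], nid[i + 1, j + 1]
            if (i + j) % 2 == 0:
                tris.append([n00, n10, n11])
                tris.append([n00, n11, n01])
            else:
                tris.append([n00, n10, n01])
                tris.append([n10, n11, n01])
    triangles = np.asarray(tris, dtype=np.int64)

    # enforce counterclockwise orientation
    p = nodes[triangles]
    twoA = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = twoA < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]

    mesh = Mesh(
        nodes=nodes,
        triangles=triangles,
        cavity_nodes=nid[0, :].copy(),
        outer_nodes=nid[-1, :].copy(),
        axis_nodes=nid[1:-1, -1].copy(),
        midplane_nodes=nid[1:-1, 0].copy(),
        min_angle_deg=0.0,
    )
    mesh.min_angle_deg = _min_angle(nodes, triangles)
    if mesh.min_angle_deg < 15.0:
        raise RuntimeError(
            f"mesh quality too low: min angle {mesh.min_angle_deg:.1f} deg < 15")
    return mesh


def _min_angle(nodes: np.ndarray, tris: np.ndarray) -> float:
    p = nodes[tris]
    ang = []
    for k in range(3):
        v1 = p[:, (k + 1) % 3] - p[:, k]
        v2 = p[:, (k + 2) % 3] - p[:, k]
        c = (v1 * v2).sum(1) / (np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
        ang.append(np.degrees(np.arccos(np.clip(c, -1, 1))))
    return float(np.min(ang))


# ---------------------------------------------------------------------------
# nonlinear solve

class _Kinematics:
    """Precomputed reference geometry for vectorized element evaluation."""

    def __init__(self, mesh: Mesh):
        X = mesh.nodes[mesh.triangles]            # (M, 3, 2)
        e1 = X[:, 1] - X[:, 0]
        e2 = X[:, 2] - X[:, 0]
        twoA = e1[:, 0] * e2[:, 1] - e2[:, 0] * e1[:, 1]
        self.area = 0.5 * twoA
        # gradients of linear shape functions: dN_i = rot(edge_opposite)/2A
        dN = np.empty((len(X), 3, 2))
        for i in range(3):
            a, b = X[:, (i + 1) % 3], X[:, (i + 2) % 3]
            dN[:, i, 0] = (a[:, 1] - b[:, 1]) / twoA
            dN[:, i, 1] = (b[:, 0] - a[:, 0]) / twoA
        self.dN = dN
        self.Rc = X[:, :, 0].mean(axis=1)         # centroid radius
        self.weight = 2.0 * np.pi * self.Rc * self.area
        self.tris = mesh.triangles


def _element_forces(kin: _Kinematics, ue: np.ndarray,
                    params: FibrousMatrixParams) -> np.ndarray:
    """Internal nodal forces per element, (M, 3, 2); total-Lagrangian, 1-pt quad."""
    G = np.einsum("mia,mib->mab", ue, kin.dN)     # grad u, (M, 2, 2)
    F2 = G.copy()
    F2[:, 0, 0] += 1.0
    F2[:, 1, 1] += 1.0
    Ftt = 1.0 + ue[:, :, 0].mean(axis=1) / kin.Rc
    sig2, sig_h = cauchy_stress_batch(F2, Ftt, params)
    det2 = F2[:, 0, 0] * F2[:, 1, 1] - F2[:, 0, 1] * F2[:, 1, 0]
    J = det2 * Ftt
    # first Piola-Kirchhoff: P = J sigma F^{-T} (block diagonal in (rz, theta))
    Finv2 = np.empty_like(F2)
    Finv2[:, 0, 0] = F2[:, 1, 1] / det2
    Finv2[:, 1, 1] = F2[:, 0, 0] / det2
    Finv2[:, 0, 1] = -F2[:, 0, 1] / det2
    Finv2[:, 1, 0] = -F2[:, 1, 0] / det2
    P2 = J[:, None, None] * sig2 @ np.swapaxes(Finv2, 1, 2)
    Ptt = J * sig_h / Ftt
    f = np.einsum("mab,mib->mia", P2, kin.dN) * kin.weight[:, None, None]
    f[:, :, 0] += (Ptt / kin.Rc * kin.weight)[:, None] / 3.0
    return f


def _assemble(kin: _Kinematics, u: np.ndarray, params: FibrousMatrixParams,
              n_nodes: int, fd_step: float, want_tangent: bool):
    ue = u[kin.tris]
    f0 = _element_forces(kin, ue, params)
    resid = np.zeros((n_nodes, 2))
    for i in range(3):
        np.add.at(resid, kin.tris[:, i], f0[:, i, :])
    if not want_tangent:
        return resid, None
    M = len(kin.tris)
    Ke = np.empty((M, 6, 6))
    for j in range(6):
        i_node, comp = divmod(j, 2)
        up = ue.copy()
        up[:, i_node, comp] += fd_step
        fj = _element_forces(kin, up, params)
        Ke[:, :, j] = (fj - f0).reshape(M, 6) / fd_step
    rows = np.repeat(kin.tris.repeat(2, axis=1) * 2
                     + np.tile([0, 1], 3), 6).reshape(M, 6, 6)
    cols = np.transpose(rows, (0, 2, 1))
    K = sparse.coo_matrix((Ke.ravel(), (rows.ravel(), cols.ravel())),
                          shape=(2 * n_nodes, 2 * n_nodes)).tocsr()
    return resid, K


def _prescribed_displacement(mesh: Mesh, cell: CellGeometry) -> np.ndarray:
    """Full cavity-surface displacement achieving the stated volume loss."""
    keep = 1.0 - cell.contraction_volume_fraction
    u = np.zeros((mesh.n_nodes, 2))
    xy = mesh.nodes[mesh.cavity_nodes]
    if cell.polarization is Polarization.isotropic:
        s = keep ** (1.0 / 3.0)
        u[mesh.cavity_nodes] = (s - 1.0) * xy
    else:  # axial: contract along the tendon axis only
        u[mesh.cavity_nodes, 1] = (keep - 1.0) * xy[:, 1]
    return u


def solve_contraction(mesh: Mesh, params: FibrousMatrixParams,
                      cell: CellGeometry, increments: int = 5,
                      newton_tol: float = 1e-8, max_newton: int = 25,
                      max_cutbacks: int = 4) -> DisplacementField:
    """Quasi-static nonlinear solve of the cavity-contraction problem.

    The cavity surface displacement is ramped in ``increments`` steps; each
    step is solved with Newton iterations (element-level finite-difference
    tangents) to a relative residual of ``newton_tol``.  Diverging steps are
    automatically subdivided up to ``max_cutbacks`` times.
    """
    if increments < 1:
        raise ValueError("increments must be >= 1")
    kin = _Kinematics(mesh)
    n = mesh.n_nodes
    u_target = _prescribed_displacement(mesh, cell)

    fixed = np.zeros((n, 2), dtype=bool)
    fixed[mesh.cavity_nodes] = True
    fixed[mesh.outer_nodes] = True
    fixed[mesh.axis_nodes, 0] = True       # u_r = 0 on the symmetry axis
    fixed[mesh.midplane_nodes, 1] = True   # u_z = 0 on the mirror midplane
    free = ~fixed.ravel()

    fd_step = 1e-6 * cell.a
    scale = max(params.kappa, params.G, params.E_f) * cell.a ** 2

    u = np.zeros((n, 2))
    t_done = 0.0
    dt = 1.0 / increments
    cutbacks = 0
    while t_done < 1.0 - 1e-12:
        t_try = min(t_done + dt, 1.0)
        u_trial = u.copy()
        u_trial[mesh.cavity_nodes] = t_try * u_target[mesh.cavity_nodes]
        converged = False
        for _ in range(max_newton):
            resid, K = _assemble(kin, u_trial, params, n, fd_step, True)
            r_free = resid.ravel()[free]
            rnorm = np.linalg.norm(r_free)
            if rnorm <= newton_tol * scale:
                converged = True
                break
            du = spsolve(K[free][:, free], -r_free)
            if not np.all(np.isfinite(du)):
                break
            u_trial.ravel()[free] += du
        if converged:
            u = u_trial
            t_done = t_try
        else:
            dt /= 2.0
            cutbacks += 1
            if cutbacks > max_cutbacks:
                raise RuntimeError(
                    f"Newton failed to converge at load fraction {t_try:.3f} "
                    f"after {max_cutbacks} increment cutbacks")
    return DisplacementField(mesh=mesh, u=u, cell=cell, params=params)


# ---------------------------------------------------------------------------
# post-processing

def radial_profile(field: DisplacementField, ray_angles_deg=None,
                   n_samples: int = 80) -> DisplacementProfile:
    """Sample |u| along rays from the cavity surface; angular average included.

    Sample points start one near-field element beyond the cavity surface and
    stop one element short of the outer boundary.  Rays are specified as
    angles in degrees from the midplane (0) to the axis (90).
    """
    mesh = field.mesh
    cell = field.cell
    if ray_angles_deg is None:
        ray_angles_deg = np.linspace(5.0, 85.0, 9)
    ray_angles_deg = np.asarray(ray_angles_deg, dtype=float)

    umag = np.linalg.norm(field.u, axis=1)
    interp = LinearNDInterpolator(mesh.nodes, umag)

    R_out = float(np.max(np.linalg.norm(mesh.nodes, axis=1)))
    # one-element margins from the boundary sizes
    d_cav = np.linalg.norm(np.diff(mesh.nodes[mesh.cavity_nodes], axis=0), axis=1)
    near = float(np.median(d_cav))
    d_out = np.linalg.norm(np.diff(mesh.nodes[mesh.outer_nodes], axis=0), axis=1)
    far = float(np.median(d_out))

    br, bz = cell.semi_axis_r, cell.semi_axis_z
    th = np.radians(ray_angles_deg)
    ct, st = np.cos(th), np.sin(th)
    rho0 = 1.0 / np.sqrt((ct / br) ** 2 + (st / bz) ** 2)   # surface radius per ray

    d_grid = np.geomspace(near, R_out - rho0.max() - far, n_samples)
    per_ray = np.empty((len(th), n_samples))
    truncated = False
    for i in range(len(th)):
        pts = np.stack([(rho0[i] + d_grid) * ct[i], (rho0[i] + d_grid) * st[i]],
                       axis=1)
        vals = interp(pts)
        if np.any(np.isnan(vals)):
            truncated = True
        per_ray[i] = vals
    u_mean = np.nanmean(per_ray, axis=0)
    r_center = float(np.mean(rho0)) + d_grid
    return DisplacementProfile(r=d_grid, r_center=r_center, u=u_mean,
                               ray_angles_deg=ray_angles_deg, per_ray_u=per_ray,
                               a=cell.a, R_out=R_out, truncated=truncated)


def fit_power_law(profile: DisplacementProfile, r_min_factor: float = 1.2,
                  r_max_factor: float = 0.5) -> DecayFit:
    """OLS of log u vs log r (distance from the cell center) -> decay exponent eta.

    Fit window: [r_min_factor * a, r_max_factor * R_out] in center distance.
    Non-positive u values inside the window are masked.
    """
    r = profile.r_center
    u = profile.u
    lo, hi = r_min_factor * profile.a, r_max_factor * profile.R_out
    mask = (r >= lo) & (r <= hi) & np.isfinite(u)
    if np.any(u[mask] <= 0):
        import warnings
        warnings.warn("non-positive displacements masked in power-law fit")
        mask &= u > 0
    if mask.sum() < 10:
        raise ValueError("fewer than 10 usable points in the fit range")
    x, y = np.log(r[mask]), np.log(u[mask])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DecayFit(eta=float(-slope), prefactor=float(np.exp(intercept)),
                    r_range=(lo, hi), r_squared=float(r2), n_points=int(mask.sum()))


def effective_decay(eta: float, cellularity: float, reference_cellularity: float,
                    density: str = "areal") -> float:
    """Cellularity-scaled decay exponent eta_eff.

    Mean inter-cell spacing scales as cellularity^(-1/2) for areal densities
    (cells per area, as counted in tissue sections) or ^(-1/3) for volumetric
    densities; eta is scaled by spacing relative to the reference so that
    groups with more cells need less transmission range per cell.  The spacing
    rule is an interpretation (recorded in run metadata by the pipeline).
    """
    if cellularity <= 0 or reference_cellularity <= 0:
        raise ValueError("cellularity must be > 0")
    expo = 0.5 if density == "areal" else 1.0 / 3.0
    return eta * (reference_cellularity / cellularity) ** expo


def linear_cavity_solution(r, a: float, R_out: float, u_a: float) -> np.ndarray:
    """Exact linear-elastic spherical-cavity displacement with fixed outer wall.

    u(r) = A r + B / r^2 with u(a) = u_a and u(R_out) = 0.  For R_out -> inf
    this reduces to the classical u = u_a (a/r)^2 decay (eta = 2).
    """
    r = np.asarray(r, dtype=float)
    B = u_a / (1.0 / a ** 2 - a / R_out ** 3)
    A = -B / R_out ** 3
    return A * r + B / r ** 2


# ---------------------------------------------------------------------------
# independent 1-D spherical oracle

def spherical_contraction_1d(params: FibrousMatrixParams, a: float, R_out: float,
                             contraction_volume_fraction: float = 0.05,
                             n_elements: int = 400, increments: int = 5,
                             newton_tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Spherically symmetric cavity contraction under the same constitutive law.

    Reduced 1-D finite-element solve of the radial two-point boundary-value
    problem (deformed radius x(R); stretches lambda_r = x', lambda_h = x/R),
    independent of the 2-D axisymmetric solver.  Returns (R_grid, u(R_grid)).
    """
    s = (1.0 - contraction_volume_fraction) ** (1.0 / 3.0)
    # graded nodes, finer at the cavity
    t = np.linspace(0.0, 1.0, n_elements + 1)
    Rg = a + (R_out - a) * t ** 1.5
    x = Rg.copy()

    mid = 0.5 * (Rg[:-1] + Rg[1:])
    dR = np.diff(Rg)

    def internal(xv):
        lam_r = np.diff(xv) / dR
        xm = 0.5 * (xv[:-1] + xv[1:])
        lam_h = xm / mid
        # principal Cauchy stresses via the batch kernel: in-plane block is
        # diag(lam_r, lam_h); hoop stretch lam_h (two equal hoop directions)
        M = len(mid)
        F2 = np.zeros((M, 2, 2))
        F2[:, 0, 0] = lam_r
        F2[:, 1, 1] = lam_h
        sig2, sig_h = cauchy_stress_batch(F2, lam_h, params)
        J = lam_r * lam_h ** 2
        P_r = J * sig2[:, 0, 0] / lam_r
        P_h = J * sig2[:, 1, 1] / lam_h
        w = 4.0 * np.pi * mid ** 2 * dR
        f = np.zeros_like(xv)
        # dPi = P_r dlam_r + 2 P_h dlam_h per element
        fr = P_r * w / dR
        fh = 2.0 * P_h * w / (2.0 * mid)
        np.add.at(f, np.arange(M), -fr + fh)
        np.add.at(f, np.arange(1, M + 1), fr + fh)
        return f

    n_free = len(x) - 2
    scale = max(params.kappa, params.G, params.E_f) * a ** 2
    for k in range(1, increments + 1):
        xa = a * (1.0 + k * (s - 1.0) / increments)
        x[0] = xa
        prev_norm = np.inf
        for _ in range(60):
            f = internal(x)
            r_free = f[1:-1]
            rnorm = np.linalg.norm(r_free)
            if rnorm <= newton_tol * scale:
                break
            if rnorm >= 0.5 * prev_norm and rnorm <= 1e4 * newton_tol * scale:
                break  # stagnated at the FD-Jacobian noise floor; accept
            prev_norm = rnorm
            h = 1e-7 * a
            # FD Jacobian by stride-3 coloring (tridiagonal connectivity)
            cols = [np.arange(1 + c, len(x) - 1, 3) for c in range(3)]
            Jcol = np.zeros((len(x), len(x)))
            for grp in cols:
                xp = x.copy()
                xp[grp] += h
                df = (internal(xp) - f) / h
                for j in grp:
                    sl = slice(max(j - 1, 0), min(j + 2, len(x)))
                    Jcol[sl, j] = df[sl]
            A = Jcol[1:-1, 1:-1]
            dx = np.linalg.solve(A + 1e-30 * np.eye(n_free), -r_free)
            x[1:-1] += dx
        else:
            raise RuntimeError("1-D spherical Newton failed to converge")
    return Rg, x - Rg
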