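"""Fibrous-matrix constitutive law: compressible neo-Hookean ground matrix plus
a strain-stiffening fiber contribution along the principal stretch directions.

The Cauchy stress decomposes as sigma = sigma_b + sigma_f with

    sigma_b = kappa (J - 1) I + G dev(Bbar) / J
    sigma_f = (1/J) sum_a f'(lambda_a) lambda_a (n_a x n_a)

where Bbar = J^(-2/3) B is the isochoric left Cauchy-Green tensor, lambda_a
are principal stretches (square roots of the eigenvalues of C) and n_a the
principal directions of B.  The fiber response f'(lambda) is zero below a
critical stretch lambda1, grows as a power n between lambda1 and lambda2
(fiber engagement / uncrimping), and transitions to a stiffened power-m
regime above lambda2.  The engaged-fiber modulus is E_f; the ratio E_f/E_b
sets how strongly fibers reinforce the isotropic background and controls how
far a contracting cell transmits displacement into the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

_EYE = np.eye(3)


class TangentSymmetryWarning(UserWarning):
    """Numerical tangent lost major symmetry (non-smooth branch crossing)."""


class IdentifiabilityWarning(UserWarning):
    """Fit is under-determined over the supplied stretch range."""


@dataclass(frozen=True)
class FibrousMatrixParams:
    """Parameters (kappa, G, E_f, lambda1, lambda2, n, m) of the fibrous law.

    ``kappa``/``G`` (MPa) are the small-strain bulk and shear moduli of the
    isotropic background; they may be constructed from an equivalent isotropic
    Young's modulus ``E_b`` and Poisson ratio ``nu`` via :meth:`from_youngs`.
    ``lambda1 < lambda2`` are the critical stretches bounding the fiber
    engagement regime, ``n`` and ``m`` the stiffening exponents.
    """

    kappa: float
    G: float
    E_f: float
    lambda1: float
    lambda2: float
    n: float
    m: float

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.G <= 0:
            raise ValueError("kappa and G must be > 0")
        if self.E_f < 0:
            raise ValueError("E_f must be >= 0")
        if not (1.0 <= self.lambda1 < self.lambda2):
            raise ValueError("require 1 <= lambda1 < lambda2")
        if self.n <= 0 or self.m <= 0:
            raise ValueError("exponents n, m must be > 0")

    @classmethod
    def from_youngs(cls, E_b: float, E_f: float, lambda1: float, lambda2: float,
                    n: float, m: float, nu: float = 0.30) -> "FibrousMatrixParams":
        """Build from the isotropic Young's modulus E_b and Poisson ratio nu."""
        kappa = E_b / (3.0 * (1.0 - 2.0 * nu))
        G = E_b / (2.0 * (1.0 + nu))
        return cls(kappa=kappa, G=G, E_f=E_f, lambda1=lambda1, lambda2=lambda2,
                   n=n, m=m)

    @property
    def E_b(self) -> float:
        """Equivalent isotropic Young's modulus 9 kappa G / (3 kappa + G)."""
        return 9.0 * self.kappa * self.G / (3.0 * self.kappa + self.G)


@dataclass
class DeformationState:
    """Kinematic quantities derived from a deformation gradient F."""

    F: np.ndarray
    J: float
    B: np.ndarray
    C: np.ndarray
    Bbar: np.ndarray
    principal_stretches: np.ndarray   # lambda_a, descending
    principal_directions: np.ndarray  # columns n_a of B

    @classmethod
    def from_F(cls, F: np.ndarray) -> "DeformationState":
        F = np.asarray(F, dtype=float)
        J = float(np.linalg.det(F))
        if J <= 0.0:
            raise ValueError(f"inverted element: det(F) = {J:.3g} <= 0")
        B = F @ F.T
        C = F.T @ F
        lam2, vecs = np.linalg.eigh(B)
        order = np.argsort(lam2)[::-1]
        return cls(F=F, J=J, B=B, C=C, Bbar=J ** (-2.0 / 3.0) * B,
                   principal_stretches=np.sqrt(lam2[order]),
                   principal_directions=vecs[:, order])


def fiber_stress_derivative(lam, params: FibrousMatrixParams):
    """Piecewise fiber response f'(lambda) in MPa; C0 and C1 at both breakpoints."""
    lam = np.asarray(lam, dtype=float)
    l1, l2, n, m, Ef = (params.lambda1, params.lambda2, params.n, params.m,
                        params.E_f)
    out = np.zeros(lam.shape)
    mid = (lam >= l1) & (lam < l2)
    if np.any(mid):
        s = (lam[mid] - l1) / (l2 - l1)
        out[mid] = Ef * s ** n * (lam[mid] - l1) / (n + 1.0)
    top = lam >= l2
    if np.any(top):
        out[top] = Ef * ((l2 - l1) / (n + 1.0)
                         + ((1.0 + lam[top] - l2) ** (m + 1.0) - 1.0) / (m + 1.0))
    return out if out.ndim else float(out)


def cauchy_stress(state: DeformationState, params: FibrousMatrixParams) -> np.ndarray:
    """Total Cauchy stress (3x3, MPa) at the given deformation state."""
    J = state.J
    dev_Bbar = state.Bbar - np.trace(state.Bbar) / 3.0 * _EYE
    sig = params.kappa * (J - 1.0) * _EYE + params.G * dev_Bbar / J
    fp = fiber_stress_derivative(state.principal_stretches, params)
    for a in range(3):
        if fp[a] != 0.0:
            na = state.principal_directions[:, a]
            sig = sig + (fp[a] * state.principal_stretches[a] / J) * np.outer(na, na)
    return sig


def cauchy_stress_batch(F2: np.ndarray, lam_h: np.ndarray,
                        params: FibrousMatrixParams) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized stress for axisymmetric states: in-plane 2x2 block + hoop.

    ``F2`` has shape (N, 2, 2) (the r-z block of F) and ``lam_h`` shape (N,)
    (the hoop stretch, itself a principal stretch).  Returns the in-plane
    Cauchy stress block (N, 2, 2) and the hoop Cauchy stress (N,).  Used by
    the finite-element solver, where the hoop direction is always principal.
    """
    detF2 = F2[:, 0, 0] * F2[:, 1, 1] - F2[:, 0, 1] * F2[:, 1, 0]
    J = detF2 * lam_h
    if np.any(J <= 0.0):
        raise ValueError("inverted element: det(F) <= 0")
    B2 = F2 @ np.swapaxes(F2, 1, 2)
    Jm23 = J ** (-2.0 / 3.0)
    trB = B2[:, 0, 0] + B2[:, 1, 1] + lam_h ** 2
    # isotropic part
    sig2 = np.zeros_like(B2)
    dev_fac = params.G * Jm23 / J
    sig2[:, 0, 0] = dev_fac * (B2[:, 0, 0] - trB / 3.0)
    sig2[:, 1, 1] = dev_fac * (B2[:, 1, 1] - trB / 3.0)
    sig2[:, 0, 1] = sig2[:, 1, 0] = dev_fac * B2[:, 0, 1]
    vol = params.kappa * (J - 1.0)
    sig2[:, 0, 0] += vol
    sig2[:, 1, 1] += vol
    sig_h = vol + dev_fac * (lam_h ** 2 - trB / 3.0)
    # fiber part: closed-form eigen of the symmetric 2x2 in-plane block
    tr2 = B2[:, 0, 0] + B2[:, 1, 1]
    disc = np.sqrt(np.maximum((B2[:, 0, 0] - B2[:, 1, 1]) ** 2
                              + 4.0 * B2[:, 0, 1] ** 2, 0.0))
    e1 = 0.5 * (tr2 + disc)
    e2 = np.maximum(0.5 * (tr2 - disc), 1e-300)
    lam1 = np.sqrt(e1)
    lam2 = np.sqrt(e2)
    # eigenvector for e1: both (B01, e1-B00) and (e1-B11, B01) are parallel to
    # it; pick the numerically larger one (robust for diagonal B, where the
    # first collapses to rounding noise).  Near-isotropic states (disc ~ 0)
    # have f1 ~ f2, so the arbitrary fallback direction is harmless.
    cand_ax = np.stack([B2[:, 0, 1], e1 - B2[:, 0, 0]], axis=1)
    cand_bx = np.stack([e1 - B2[:, 1, 1], B2[:, 0, 1]], axis=1)
    na_ = np.linalg.norm(cand_ax, axis=1)
    nb_ = np.linalg.norm(cand_bx, axis=1)
    use_b = nb_ >= na_
    vx = np.where(use_b, cand_bx[:, 0], cand_ax[:, 0])
    vy = np.where(use_b, cand_bx[:, 1], cand_ax[:, 1])
    nrm = np.sqrt(vx ** 2 + vy ** 2)
    degen = nrm <= 1e-12 * np.sqrt(tr2)
    vx = np.where(degen, 1.0, vx)
    vy = np.where(degen, 0.0, vy)
    nrm = np.where(degen, 1.0, nrm)
    vx, vy = vx / nrm, vy / nrm
    f1 = fiber_stress_derivative(lam1, params) * lam1 / J
    f2 = fiber_stress_derivative(lam2, params) * lam2 / J
    sig2[:, 0, 0] += f1 * vx ** 2 + f2 * vy ** 2
    sig2[:, 1, 1] += f1 * vy ** 2 + f2 * vx ** 2
    off = (f1 - f2) * vx * vy
    sig2[:, 0, 1] += off
    sig2[:, 1, 0] += off
    sig_h = sig_h + fiber_stress_derivative(lam_h, params) * lam_h / J
    return sig2, sig_h


def uniaxial_response(stretch_grid, params: FibrousMatrixParams,
                      tol: float = 1e-10) -> np.ndarray:
    """Axial Cauchy stress (MPa) under uniaxial stress at each axial stretch.

    The lateral stretch at every grid point is solved simultaneously
    (vectorized Newton with a bisection fallback) so that the transverse
    Cauchy stress vanishes.  The grid must start at or above 1 and be
    nondecreasing.
    """
    grid = np.asarray(stretch_grid, dtype=float)
    if np.any(grid < 1.0) or np.any(np.diff(grid) < 0):
        raise ValueError("stretch grid must be >= 1 and nondecreasing")

    def transverse(a, lam):
        # F = diag(lam, a, a): in-plane block (axial, lateral); hoop = lateral
        n = lam.size
        F2 = np.zeros((n, 2, 2))
        F2[:, 0, 0] = lam
        F2[:, 1, 1] = a
        sig2, _ = cauchy_stress_batch(F2, a, params)
        return sig2[:, 1, 1]

    scale = max(params.kappa, params.G, params.E_f, 1.0)
    a = np.ones(grid.shape)
    active = grid > 1.0
    for _ in range(80):
        if not np.any(active):
            break
        f0 = transverse(a[active], grid[active])
        conv = np.abs(f0) < tol * scale
        idx = np.flatnonzero(active)
        active[idx[conv]] = False
        if not np.any(active):
            break
        rem = np.flatnonzero(active)
        h = 1e-7
        d = (transverse(a[rem] + h, grid[rem]) - f0[~conv]) / h
        d = np.where(d == 0.0, 1.0, d)
        step = np.clip(f0[~conv] / d, -0.1, 0.1)
        # physical root under axial tension: lateral contraction, a in (0, 1]
        a[rem] = np.clip(a[rem] - step, 0.05, 1.0)
    else:
        for i in np.flatnonzero(active):
            lam_i = np.array([grid[i]])
            f = lambda ai: transverse(np.array([ai]), lam_i)[0]
            if f(0.05) * f(1.0) > 0:
                raise RuntimeError(
                    f"lateral-stretch solve failed at axial stretch {grid[i]:.4f}")
            a[i] = optimize.brentq(f, 0.05, 1.0, xtol=1e-14)

    n = grid.size
    F2 = np.zeros((n, 2, 2))
    F2[:, 0, 0] = grid
    F2[:, 1, 1] = a
    sig2, _ = cauchy_stress_batch(F2, a, params)
    out = sig2[:, 0, 0]
    out[grid == 1.0] = 0.0
    return out


# ---------------------------------------------------------------------------
# numerical tangent

_VOIGT = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def numerical_tangent(state: DeformationState, params: FibrousMatrixParams,
                      h: float = 1e-6, sym_tol: float = 1e-6) -> np.ndarray:
    """Central-difference spatial tangent as a 6x6 matrix.

    Voigt ordering (11, 22, 33, 12, 13, 23).  Column J perturbs the current
    configuration by the symmetric velocity-gradient basis tensor D_J:
    F± = (I ± h/2 D_J) F, and the column holds the Voigt components of
    d(tau)/dh where tau = J sigma is the Kirchhoff stress.  For a smooth
    hyperelastic state this matrix has major symmetry; loss of symmetry beyond
    ``sym_tol`` (relative) raises :class:`TangentSymmetryWarning` and signals
    a non-smooth fiber branch crossing.
    """
    if not (1e-8 <= h <= 1e-4):
        raise ValueError("h must lie in [1e-8, 1e-4]")
    F = state.F
    C = np.empty((6, 6))
    for col, (i, j) in enumerate(_VOIGT):
        D = np.zeros((3, 3))
        D[i, j] += 0.5
        D[j, i] += 0.5
        tau_p = _kirchhoff((_EYE + 0.5 * h * D) @ F, params)
        tau_m = _kirchhoff((_EYE - 0.5 * h * D) @ F, params)
        dtau = (tau_p - tau_m) / h
        C[:, col] = [dtau[a, b] for a, b in _VOIGT]
    scale = np.max(np.abs(C)) or 1.0
    asym = np.max(np.abs(C - C.T)) / scale
    if asym > sym_tol:
        warnings.warn(f"tangent asymmetry {asym:.2e} exceeds {sym_tol:.0e}; "
                      "state likely straddles a fiber branch point",
                      TangentSymmetryWarning)
    return C


def _kirchhoff(F: np.ndarray, params: FibrousMatrixParams) -> np.ndarray:
    st = DeformationState.from_F(F)
    return st.J * cauchy_stress(st, params)


# ---------------------------------------------------------------------------
# parameter fitting

@dataclass
class MatrixFit:
    params: FibrousMatrixParams
    nu: float
    residuals: np.ndarray
    rmse: float
    jacobian_condition: float
    warnings: list[str]


def fit_matrix_params(stretch, stress, nu: float = 0.30,
                      fixed: dict[str, float] | None = None) -> MatrixFit:
    """Fit (E_b, E_f, lambda1, lambda2, n, m) to a uniaxial stress-stretch curve.

    Bounded least squares in log/offset coordinates with deterministic
    multistart.  ``fixed`` pins any subset of the six parameters.  Curves that
    never engage the fibers (max stretch below the fitted lambda1) leave
    (E_f, lambda2, n, m) unidentifiable; this is reported via warnings rather
    than an exception.
    """
    stretch = np.asarray(stretch, dtype=float)
    stress = np.asarray(stress, dtype=float)
    fixed = dict(fixed or {})
    span = stretch.max() - 1.0
    if span <= 0:
        raise ValueError("curve must extend beyond stretch 1")

    # initial slope -> E_b guess (uniaxial small-strain modulus is E_b)
    lo = stretch <= 1.0 + 0.2 * span
    slope0 = np.polyfit(stretch[lo], stress[lo], 1)[0] if lo.sum() >= 2 else \
        stress.max() / span
    slope0 = max(slope0, 1e-6)
    hi = stretch >= stretch.max() - 0.2 * span
    slope1 = max(np.polyfit(stretch[hi], stress[hi], 1)[0], slope0) \
        if hi.sum() >= 2 else slope0

    names = ["E_b", "E_f", "lambda1", "lambda2", "n", "m"]

    def build(theta_free):
        vals = {}
        it = iter(theta_free)
        for nm in names:
            vals[nm] = fixed[nm] if nm in fixed else next(it)
        return vals

    free = [nm for nm in names if nm not in fixed]

    def unpack(vals):
        # internal coords: log E_b, log E_f, lambda1, log(lambda2-lambda1), log n, log m
        return FibrousMatrixParams.from_youngs(
            E_b=np.exp(vals["E_b"]) if "E_b" in free else vals["E_b"],
            E_f=np.exp(vals["E_f"]) if "E_f" in free else vals["E_f"],
            lambda1=vals["lambda1"],
            lambda2=vals["lambda1"] + (np.exp(vals["lambda2"]) if "lambda2" in free
                                       else vals["lambda2"] - vals["lambda1"]),
            n=np.exp(vals["n"]) if "n" in free else vals["n"],
            m=np.exp(vals["m"]) if "m" in free else vals["m"], nu=nu)

    def resid(theta_free):
        try:
            p = unpack(build(theta_free))
            return uniaxial_response(stretch, p) - stress
        except (ValueError, RuntimeError):
            return np.full(stretch.size, 1e6)

    # data-driven breakpoint guesses from the tangent-modulus profile
    dsl = np.gradient(stress, stretch)
    above = stretch[dsl >= 2.0 * slope0]
    l1_est = float(above[0]) if above.size else 1.0 + 0.3 * span
    mid_slope = 0.5 * (slope0 + dsl.max())
    above2 = stretch[dsl >= mid_slope]
    l2_est = float(above2[0]) if above2.size else min(l1_est + 0.3 * span,
                                                      stretch.max())
    l2_est = max(l2_est, l1_est + 0.02 * span)

    starts = []
    for l1 in (l1_est, 1.0 + 0.5 * (l1_est - 1.0), 1.0 + 0.4 * span):
        for n0 in (2.0, 5.0):
            init = {"E_b": np.log(slope0), "E_f": np.log(max(slope1 - slope0, slope0)),
                    "lambda1": l1, "lambda2": np.log(max(l2_est - l1, 0.02 * span)),
                    "n": np.log(n0), "m": np.log(8.0)}
            starts.append([init[nm] for nm in free])

    lb, ub = [], []
    bnd = {"E_b": (np.log(1e-8), np.log(1e6)), "E_f": (np.log(1e-8), np.log(1e8)),
           "lambda1": (1.0, 1.0 + 2.0 * span), "lambda2": (np.log(1e-4), np.log(2.0)),
           "n": (np.log(0.1), np.log(50.0)), "m": (np.log(0.1), np.log(200.0))}
    for nm in free:
        lb.append(bnd[nm][0])
        ub.append(bnd[nm][1])

    best = None
    for th0 in starts:
        try:
            res = optimize.least_squares(resid, th0, bounds=(lb, ub),
                                         xtol=1e-12, ftol=1e-12, max_nfev=400)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("matrix-parameter fit failed from all starts")

    p = unpack(build(best.x))
    msgs: list[str] = []
    J = best.jac
    sv = np.linalg.svd(J, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if cond > 1e8:
        msgs.append(f"ill-conditioned fit (Jacobian condition {cond:.2e})")
    if stretch.max() < p.lambda1:
        msgs.append("max stretch below lambda1: E_f, lambda2, n, m unidentifiable")
    elif stretch.max() < p.lambda2:
        msgs.append("max stretch below lambda2: m (and partly lambda2) unidentifiable")
    for msg in msgs:
        warnings.warn(msg, IdentifiabilityWarning)
    r = resid(best.x)
    return MatrixFit(params=p, nu=nu, residuals=r,
                     rmse=float(np.sqrt(np.mean(r ** 2))),
                     jacobian_condition=cond, warnings=msgs)
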