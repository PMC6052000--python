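"""Synthetic-data generators for every input the pipeline consumes.

Each generator is a forward model of one measurement with known ground
truth:

* force-displacement records under the cyclic/ramp/hold/sweep protocol,
  driven by the Gaussian slack-length recruitment model (fatigue damage
  enters as an increase in mean slack length after high-magnitude cycling);
* polarized-light stacks whose per-region intensity follows the
  sin^2(2(theta_p - theta_f)) crossed-polarizer response, with fiber angles
  drawn from an axial von Mises distribution;
* SHG-like images of anti-aliased fiber segments with von Mises orientations;
* fields of non-overlapping elliptical nuclei with controlled aspect-ratio
  and angular dispersion;
* regression tables with known coefficients, controlled collinearity and
  optional AR(1) residuals.

All randomness flows through explicit integer seeds (no global state), and
angular dispersion uses the von Mises distribution on doubled/quadrupled
angles — the standard axial-data construction.  Noise is additive Gaussian
on force and pixel intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import line_aa, ellipse as draw_ellipse

from .recruitment import RecruitmentParams, recruitment_force


class ProtocolError(ValueError):
    pass


class InsufficientSamplingError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


@dataclass(frozen=True)
class LoadingProtocol:
    """Cyclic loading and diagnostic protocol applied to one specimen.

    Defaults mirror the standard protocol: preconditioning, dynamic loading
    at 1 Hz for 0/10/1000 cycles, a 0.1 %/s quasi-static ramp to 1% or 10%
    strain, a stress-relaxation hold, and a frequency sweep of 0.125% strain
    amplitude at 0.1, 1, 5 and 10 Hz; optionally a 1000 s recovery hold at
    0% strain.
    """

    precondition_cycles: int = 10
    cyclic_magnitude: str = "zero"          # zero | low | high
    cycle_count: int = 0                    # 0 | 10 | 1000
    frequency: float = 1.0                  # Hz
    ramp_rate: float = 0.1                  # % strain / s
    target_strain: float = 10.0             # % (1 or 10)
    sweep_amplitude: float = 0.125          # % strain
    sweep_frequencies: tuple = (0.1, 1.0, 5.0, 10.0)
    recovery_hold: float = 0.0              # s (0 or 1000)
    hold_duration: float = 100.0            # s stress-relaxation hold

    def __post_init__(self) -> None:
        if self.cycle_count not in (0, 10, 1000):
            raise ProtocolError("cycle_count must be one of 0, 10, 1000")
        if self.target_strain not in (1.0, 10.0, 1, 10):
            raise ProtocolError("target_strain must be 1 or 10 (%)")
        if self.cyclic_magnitude not in ("zero", "low", "high"):
            raise ProtocolError("cyclic_magnitude must be zero/low/high")
        if any(f <= 0 for f in self.sweep_frequencies) or self.frequency <= 0:
            raise ProtocolError("frequencies must be strictly positive")
        if self.cyclic_magnitude == "zero" and self.cycle_count != 0:
            raise ProtocolError("zero-magnitude loading implies 0 cycles")


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind every generated measurement.

    Mechanics: recruitment population (mm, N/mm), specimen geometry, the
    viscoelastic phase lag injected into sweeps (rad), equilibrium-relaxation
    fraction, and fatigue-damage slopes (fractional increase in mu/sigma per
    decade of high-magnitude cycles).  Imaging: axial fiber/nucleus angle
    distributions (deg; von Mises concentrations).  Regression: coefficient
    vector and residual SD of the linear generative model.
    """

    # recruitment + specimen
    mu: float = 0.15                # mm
    sigma: float = 0.05             # mm
    K_tot: float = 20.0             # N/mm
    gauge_length: float = 5.0       # mm
    area: float = 0.4               # mm^2
    # viscoelasticity
    phase_lag: float = 0.10         # rad injected in sweeps
    relax_fraction: float = 0.6     # equilibrium / peak force during holds
    relax_tau: float = 8.0          # s
    # fatigue damage (applied per decade of high-magnitude cycles)
    damage_mu_per_decade: float = 0.10
    damage_sigma_per_decade: float = 0.05
    laxity_drift_per_cycle: float = 1e-4   # mm peak drift per cycle (high mag.)
    # fiber organization (degrees / dimensionless concentration)
    fiber_mean_angle: float = 0.0
    fiber_concentration: float = 4.0
    # nuclei
    nuclei_count: int = 150
    nAR_mean: float = 2.6
    nAR_sd: float = 0.4
    nuclei_concentration: float = 3.0
    # regression
    regression_noise_sd: float = 1.0

    def damaged_recruitment(self, magnitude: str, cycles: int) -> RecruitmentParams:
        """Post-loading slack-length population: high-magnitude cycling shifts
        mu (and widens sigma) proportionally to log10(cycles)."""
        mu, sg = self.mu, self.sigma
        if magnitude == "high" and cycles > 0:
            decades = np.log10(cycles)
            mu = mu * (1.0 + self.damage_mu_per_decade * decades)
            sg = sg * (1.0 + self.damage_sigma_per_decade * decades)
        return RecruitmentParams.from_total_stiffness(mu, sg, self.K_tot)


# ---------------------------------------------------------------------------
# force-displacement records

_CYCLIC_STRAIN = {"low": (1.0, 3.0), "high": (4.0, 8.0)}   # % strain bounds


def gen_force_displacement(truth: SyntheticTruth, protocol: LoadingProtocol,
                           noise_sd: float = 0.0, seed: int = 0,
                           sample_rate: float = 100.0):
    """Generate a labeled force-displacement record under ``protocol``.

    Force on monotone paths follows the expectation-mode recruitment model;
    holds relax exponentially toward ``relax_fraction`` of the peak force;
    sweep segments superpose a strain sinusoid whose force response lags by
    the injected ``phase_lag``.  Additive Gaussian force noise of ``noise_sd``
    (N).  Deterministic for a given seed.
    """
    from .mechanics import ForceDisplacementRecord

    if noise_sd < 0:
        raise ProtocolError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    gl = truth.gauge_length
    pre_params = RecruitmentParams.from_total_stiffness(truth.mu, truth.sigma,
                                                        truth.K_tot)
    post_params = truth.damaged_recruitment(protocol.cyclic_magnitude,
                                            protocol.cycle_count)

    t_parts, d_parts, f_parts, labels = [], [], [], []
    t0 = 0.0

    def add(t, d, f, label):
        nonlocal t0
        t_parts.append(t + t0)
        d_parts.append(d)
        f_parts.append(f)
        labels.append(np.full(len(t), label, dtype=object))
        t0 = t0 + (t[-1] + (t[1] - t[0]) if len(t) > 1 else 1.0 / sample_rate)

    def sine_cycles(n_cycles, lo_mm, hi_mm, freq, params, label, drift=0.0):
        rate = max(sample_rate, 20.0 * freq)
        n = int(round(n_cycles * rate / freq))
        t = np.arange(n) / rate
        mid, amp = 0.5 * (hi_mm + lo_mm), 0.5 * (hi_mm - lo_mm)
        cyc = np.floor(t * freq)
        d = mid + amp * np.sin(2 * np.pi * freq * t - np.pi / 2) + drift * cyc
        f = recruitment_force(d, params)
        add(t, d, f, label)

    # preconditioning: small cycles in the low-toe region
    if protocol.precondition_cycles > 0:
        sine_cycles(protocol.precondition_cycles, 0.0, 0.005 * gl,
                    protocol.frequency, pre_params, "precondition")

    # dynamic loading
    if protocol.cycle_count > 0:
        lo, hi = _CYCLIC_STRAIN[protocol.cyclic_magnitude]
        drift = (truth.laxity_drift_per_cycle
                 if protocol.cyclic_magnitude == "high" else
                 0.25 * truth.laxity_drift_per_cycle)
        sine_cycles(protocol.cycle_count, lo / 100 * gl, hi / 100 * gl,
                    protocol.frequency, pre_params, "cyclic", drift)

    # quasi-static ramps with holds and sweeps at 1% then target strain
    levels = [1.0, protocol.target_strain] if protocol.target_strain > 1 else [1.0]
    d_prev = 0.0
    for level in levels:
        d_target = level / 100.0 * gl
        ramp_speed = protocol.ramp_rate / 100.0 * gl           # mm/s
        dur = (d_target - d_prev) / ramp_speed
        n = max(int(round(dur * sample_rate)), 2)
        t = np.arange(n) / sample_rate
        d = d_prev + ramp_speed * t
        add(t, d, recruitment_force(d, post_params), f"ramp_{level:g}")
        d_prev = d_target

        # stress-relaxation hold
        n = int(round(protocol.hold_duration * sample_rate))
        t = np.arange(n) / sample_rate
        f_peak = recruitment_force(d_target, post_params)
        f_hold = f_peak * (truth.relax_fraction + (1 - truth.relax_fraction)
                           * np.exp(-t / truth.relax_tau))
        add(t, np.full(n, d_target), f_hold, f"hold_{level:g}")

        # frequency sweep about the held strain
        amp_mm = protocol.sweep_amplitude / 100.0 * gl
        k_loc = (recruitment_force(d_target + 1e-6, post_params)
                 - recruitment_force(d_target - 1e-6, post_params)) / 2e-6
        f_eq = f_peak * truth.relax_fraction
        for freq in protocol.sweep_frequencies:
            rate = max(sample_rate, 50.0 * freq)
            n = int(round(5.0 / freq * rate))
            t = np.arange(n) / rate
            w = 2 * np.pi * freq
            d = d_target + amp_mm * np.sin(w * t)
            f = f_eq + k_loc * amp_mm * np.sin(w * t + truth.phase_lag)
            add(t, d, f, f"sweep_{freq:g}@{level:g}")

    if protocol.recovery_hold > 0:
        n = int(round(protocol.recovery_hold * sample_rate))
        t = np.arange(n) / sample_rate
        add(t, np.zeros(n), np.zeros(n), "recovery")

    time = np.concatenate(t_parts)
    disp = np.concatenate(d_parts)
    force = np.concatenate(f_parts)
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, force.shape)
    return ForceDisplacementRecord(
        time=time, displacement=disp, force=force, gauge_length=gl,
        cross_sectional_area=truth.area,
        segment_labels=np.concatenate(labels))


# ---------------------------------------------------------------------------
# axial von Mises angles

def sample_axial_angles(rng: np.random.Generator, mean_deg: float,
                        concentration: float, n: int,
                        period_deg: float = 180.0) -> np.ndarray:
    """Axial angles (deg) from a von Mises distribution on the scaled circle.

    Angles are drawn on the doubled (period 180) or quadrupled (period 90)
    circle and folded back, giving dispersion about ``mean_deg`` with the
    stated concentration; ``concentration`` = 0 is the uniform (isotropic)
    case.  Result lies in (mean - period/2, mean + period/2].
    """
    k = 360.0 / period_deg
    if concentration > 0:
        psi = rng.vonmises(0.0, concentration, n)
    else:
        psi = rng.uniform(-np.pi, np.pi, n)
    return mean_deg + np.degrees(psi) / k


def axial_csd_deg(concentration: float, period_deg: float = 180.0) -> float:
    """Closed-form circular SD (deg) of the axial von Mises distribution.

    On the scaled circle Rbar = I1(kappa)/I0(kappa); CSD on the original
    angle scale is sqrt(-2 ln Rbar) / k in radians.
    """
    from scipy.special import i0, i1
    k = 360.0 / period_deg
    if concentration <= 0:
        return np.inf
    rbar = i1(concentration) / i0(concentration)
    return float(np.degrees(np.sqrt(-2.0 * np.log(rbar))) / k)


# ---------------------------------------------------------------------------
# polarized-light stacks

@dataclass
class PolarizerStackTruth:
    angles_deg: np.ndarray        # polarizer angles, one per image
    theta_f: np.ndarray           # per-region true fiber angle (deg)
    region_shape: tuple[int, int]


def gen_polarizer_stack(mean_angle: float, concentration: float,
                        n_angles: int = 30, region_grid=(10, 10),
                        region_px: int = 10, noise_sd: float = 0.0,
                        seed: int = 0, amplitude: float = 120.0,
                        offset: float = 40.0):
    """Crossed-polarizer image stack with per-region fiber angles.

    Each region (``region_px`` square) has a true fiber angle drawn from the
    axial von Mises distribution (period 90 deg after wrapping); pixel
    intensity at polarizer angle theta_p is
    A sin^2(2 (theta_p - theta_f)) + B plus Gaussian noise.  Returns
    (stack, truth) where stack is (n_angles, H, W) float and truth carries
    the polarizer angles and ground-truth angle grid.
    """
    if n_angles < 4:
        raise InsufficientSamplingError("need >= 4 polarizer angles")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    rng = np.random.default_rng(seed)
    nr, nc = region_grid
    if np.isinf(concentration):
        theta_f = np.full(nr * nc, mean_angle)
    else:
        theta_f = sample_axial_angles(rng, mean_angle, concentration,
                                      nr * nc, period_deg=90.0)
    theta_f = theta_f.reshape(nr, nc)
    angles = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    H, W = nr * region_px, nc * region_px
    tf_px = np.kron(theta_f, np.ones((region_px, region_px)))
    stack = np.empty((n_angles, H, W))
    for i, ap in enumerate(angles):
        img = amplitude * np.sin(np.radians(2.0 * (ap - tf_px))) ** 2 + offset
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        stack[i] = img
    return stack, PolarizerStackTruth(angles_deg=angles, theta_f=theta_f,
                                      region_shape=(nr, nc))


def save_polarizer_stack(stack: np.ndarray, truth: PolarizerStackTruth,
                         path) -> None:
    """Write a multi-page TIFF plus a JSON sidecar of polarizer angles."""
    import json
    from pathlib import Path
    import tifffile
    tifffile.imwrite(path, stack.astype(np.float32))
    Path(str(path)).with_suffix(".json").write_text(
        json.dumps({"angles_deg": truth.angles_deg.tolist()}))


def load_polarizer_stack(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a stack written by :func:`save_polarizer_stack`."""
    import json
    from pathlib import Path
    import tifffile
    stack = tifffile.imread(path).astype(float)
    meta = json.loads(Path(str(path)).with_suffix(".json").read_text())
    return stack, np.asarray(meta["angles_deg"], dtype=float)


# ---------------------------------------------------------------------------
# SHG-like fiber images

def gen_shg_image(mean_angle: float, concentration: float,
                  fiber_density: float = 0.004, seed: int = 0,
                  shape=(256, 256), fiber_length: float = 60.0,
                  angles: np.ndarray | None = None):
    """Render anti-aliased fiber segments with von Mises axial orientations.

    ``fiber_density`` is segments per pixel of image area.  Returns
    (image, truth_angles_deg).  Angles may be supplied explicitly (e.g. two
    delta populations) instead of sampled.
    """
    if fiber_density <= 0:
        raise ValueError("fiber_density must be > 0 (empty image)")
    rng = np.random.default_rng(seed)
    H, W = shape
    n_fibers = max(int(round(fiber_density * H * W)), 1)
    if angles is None:
        if np.isinf(concentration):
            angles = np.full(n_fibers, mean_angle)
        else:
            angles = sample_axial_angles(rng, mean_angle, concentration,
                                         n_fibers, period_deg=180.0)
    img = np.zeros(shape)
    half = fiber_length / 2.0
    for ang in angles:
        cy = rng.uniform(0, H)
        cx = rng.uniform(0, W)
        # image rows grow downward: angle measured counterclockwise from +x
        dy = -np.sin(np.radians(ang)) * half
        dx = np.cos(np.radians(ang)) * half
        r0, c0 = int(round(cy - dy)), int(round(cx - dx))
        r1, c1 = int(round(cy + dy)), int(round(cx + dx))
        r0, r1 = np.clip([r0, r1], 0, H - 1)
        c0, c1 = np.clip([c0, c1], 0, W - 1)
        rr, cc, val = line_aa(r0, c0, r1, c1)
        img[rr, cc] = np.maximum(img[rr, cc], val)
    return img, np.asarray(angles, dtype=float)


# ---------------------------------------------------------------------------
# nuclei fields

def gen_nuclei_image(count: int, nAR_mean: float = 2.6, nAR_sd: float = 0.4,
                     angle_concentration: float = 3.0, mean_angle: float = 0.0,
                     seed: int = 0, shape=(512, 512), area_px: float = 120.0,
                     max_tries: int = 20000):
    """Non-overlapping elliptical nuclei on a dark background.

    Each nucleus has fixed pixel area ``area_px``, aspect ratio drawn from a
    truncated normal (>= 1), and axial von Mises orientation.  Returns
    (labeled_image, truth) with truth a DataFrame of centers, semi-axes,
    angle (deg) and aspect ratio.  Raises :class:`PlacementError` when the
    requested count cannot be placed without overlap.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    tries = 0
    placed = 0
    while placed < count:
        if tries > max_tries:
            raise PlacementError(
                f"placed only {placed}/{count} nuclei after {max_tries} tries")
        tries += 1
        ar = max(rng.normal(nAR_mean, nAR_sd), 1.0)
        b = np.sqrt(area_px / (np.pi * ar))    # minor semi-axis
        a = ar * b                             # major semi-axis
        if np.isinf(angle_concentration):
            ang = mean_angle
        else:
            ang = sample_axial_angles(rng, mean_angle, angle_concentration, 1,
                                      period_deg=180.0)[0]
        margin = a + 2
        cy = rng.uniform(margin, H - margin)
        cx = rng.uniform(margin, W - margin)
        # rotation: skimage.draw.ellipse rotates counterclockwise in (row, col);
        # our angle is ccw from +x in image (x right, y up) -> negate for rows
        rr, cc = draw_ellipse(cy, cx, b, a, shape=shape,
                              rotation=np.radians(ang))
        if np.any(labels[rr, cc] > 0):
            continue
        placed += 1
        labels[rr, cc] = placed
        rows.append({"label": placed, "cy": cy, "cx": cx,
                     "major_semi_axis": a, "minor_semi_axis": b,
                     "angle_deg": ((ang + 90) % 180) - 90, "nAR": ar})
    return labels, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regression tables

SCHEMA_NUMERIC = ["s_eq", "delta_s_eq", "E_star", "tan_delta", "CSD",
                  "delta_CSD", "cellularity", "f_actin", "SL_mn", "nCSD",
                  "delta_nCSD"]
SCHEMA_CATEGORICAL = {"healing": ("uninjured", "wk2", "wk6"),
                      "loading": ("quasi", "low", "high")}


def gen_regression_table(n: int, coefficients: dict[str, float],
                         collinearity: np.ndarray | float = 0.0,
                         resid_sd: float = 1.0, ar1_rho: float = 0.0,
                         seed: int = 0, outcome: str = "nAR",
                         numeric: list[str] | None = None,
                         categorical_effects: dict[str, dict[str, float]]
                         | None = None) -> pd.DataFrame:
    """Multiscale-variable table with a known linear generative model.

    Numeric predictors are standard multivariate normal with the given
    correlation (scalar = common pairwise correlation); categorical healing
    and loading columns are assigned cyclically.  The outcome is the linear
    combination given by ``coefficients`` (and ``categorical_effects``, as
    level -> additive shift) plus residuals of SD ``resid_sd``, AR(1) with
    coefficient ``ar1_rho`` when nonzero.
    """
    numeric = list(numeric if numeric is not None else SCHEMA_NUMERIC)
    rng = np.random.default_rng(seed)
    p = len(numeric)
    if np.isscalar(collinearity):
        C = np.full((p, p), float(collinearity))
        np.fill_diagonal(C, 1.0)
    else:
        C = np.asarray(collinearity, dtype=float)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as e:
        raise ValueError("collinearity matrix is not positive definite") from e
    X = rng.standard_normal((n, p)) @ L.T
    df = pd.DataFrame(X, columns=numeric)
    for col, levels in SCHEMA_CATEGORICAL.items():
        # balanced but independently shuffled assignment per factor
        reps = np.tile(levels, n // len(levels) + 1)[:n]
        df[col] = rng.permutation(reps)

    y = np.zeros(n)
    for name, beta in coefficients.items():
        y += beta * df[name].to_numpy()
    for col, effects in (categorical_effects or {}).items():
        y += df[col].map(lambda lv: effects.get(lv, 0.0)).to_numpy()
    eps = rng.standard_normal(n) * resid_sd
    if ar1_rho != 0.0:
        e = np.empty(n)
        e[0] = eps[0]
        for i in range(1, n):
            e[i] = ar1_rho * e[i - 1] + np.sqrt(1 - ar1_rho ** 2) * eps[i]
        eps = e
    df[outcome] = y + eps
    return df


def gen_schema_table(n: int = 100, seed: int = 0,
                     resid_sd: float = 0.5) -> tuple[pd.DataFrame, set[str]]:
    """Schema-faithful table where nAR is driven by cellularity, nCSD and healing.

    Effect sizes are strong (standardized ~1) relative to ``resid_sd``,
    emulating the finding that cellularity, nuclear disorganization and
    healing predict baseline nuclear aspect ratio.  Returns the table and the
    true support {cellularity, nCSD, healing}.
    """
    coeffs = {"cellularity": 0.6, "nCSD": -0.5}
    cat = {"healing": {"uninjured": 0.0, "wk2": -1.2, "wk6": -0.8}}
    df = gen_regression_table(n, coeffs, collinearity=0.2, resid_sd=resid_sd,
                              seed=seed, categorical_effects=cat)
    return df, {"cellularity", "nCSD", "healing"}
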