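"""Collagen and nuclear organization metrics from image data.

Polarized light: images are divided into small averaging regions; within
each region the intensity-vs-polarizer-angle curve is fitted with
A sin^2(2 (theta_p - theta_f)) + B, whose minimum locates the local fiber
direction.  The dispersion of region angles is summarized by the circular
standard deviation (CSD) — larger CSD means more disorganized collagen —
and the strain at which fibers re-align is found as the breakpoint of a
bilinear CSD-vs-strain fit.

SHG/confocal: per-window dominant fiber orientation from the second moments
of the Fourier power spectrum (the spectral principal axis is perpendicular
to the fiber direction), histogrammed and summarized by CSD (period 180).
Nuclei are segmented by global threshold + connected components; the
second-moment ellipse of each component yields the nuclear aspect ratio
(nAR = major/minor) and orientation, with nCSD the circular SD of nucleus
angles.  F-actin content is the thresholded positive-pixel fraction per ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from skimage import exposure, filters, measure


@dataclass
class CircularStats:
    """Circular mean and SD of axial angle data with the stated period (deg)."""

    mean_deg: float
    csd_deg: float
    period_deg: float
    n: int
    resultant_length: float
    degenerate: bool = False


@dataclass
class OrientationFit:
    theta_deg: float          # fiber angle, wrapped to (-period/2, period/2]
    amplitude: float          # A of the sin^2 response
    offset: float             # B
    rms_residual: float
    low_signal: bool


@dataclass
class BilinearFit:
    transition: float         # breakpoint (strain %)
    slope_low: float
    slope_high: float
    intercept: float
    sse: float
    degenerate: bool


def region_grid(shape: tuple[int, int], region_area_px2: float = 100.0,
                spacing_px: int = 20) -> list[tuple[slice, slice]]:
    """Square averaging regions of the given area at the given center spacing.

    The default (area 100 px^2 -> 10x10 px regions, centers every 20 px)
    matches the standard noise-filtering grid for polarized-light maps.
    """
    side = max(int(round(np.sqrt(region_area_px2))), 1)
    H, W = shape
    if side > H or side > W:
        raise ValueError(f"image {shape} smaller than one {side}x{side} region")
    half = side // 2
    rows = np.arange(half, H - (side - half) + 1, spacing_px)
    cols = np.arange(half, W - (side - half) + 1, spacing_px)
    return [(slice(r - half, r - half + side), slice(c - half, c - half + side))
            for r in rows for c in cols]


def region_means(stack: np.ndarray,
                 regions: list[tuple[slice, slice]]) -> np.ndarray:
    """Mean intensity per region per stack image, shape (n_images, n_regions)."""
    return np.stack([[img[rs, cs].mean() for rs, cs in regions]
                     for img in stack])


def fit_region_orientation(intensities: np.ndarray, angles_deg: np.ndarray,
                           signal_factor: float = 3.0) -> OrientationFit:
    """Fit I(theta_p) = A sin^2(2 (theta_p - theta_f)) + B for one region.

    Using sin^2(x) = (1 - cos 2x)/2 the model is linear in
    (1, cos 4 theta_p, sin 4 theta_p), so the fit is exact least squares.
    theta_f (the intensity minimum) is wrapped to (-45, 45] about the loading
    axis.  Regions whose fitted amplitude is not clearly above the residual
    noise are flagged low-signal and should be excluded from CSD.
    """
    th = np.radians(np.asarray(angles_deg, dtype=float))
    y = np.asarray(intensities, dtype=float)
    if len(np.unique(np.round(th, 12))) < 4:
        raise ValueError("need >= 4 distinct polarizer angles")
    X = np.column_stack([np.ones_like(th), np.cos(4 * th), np.sin(4 * th)])
    (c0, c1, c2), *_ = np.linalg.lstsq(X, y, rcond=None)
    # I = c0 + c1 cos4t + c2 sin4t = (B + A/2) - (A/2) cos(4 (t - theta_f))
    half_amp = np.hypot(c1, c2)
    theta_f = np.degrees(np.arctan2(-c2, -c1) / 4.0)
    theta_f = ((theta_f + 45.0) % 90.0) - 45.0
    resid = y - X @ np.array([c0, c1, c2])
    rms = float(np.sqrt(np.mean(resid ** 2)))
    A = 2.0 * half_amp
    low = A < signal_factor * rms or A <= 1e-12 * max(abs(c0), 1.0)
    return OrientationFit(theta_deg=float(theta_f), amplitude=float(A),
                          offset=float(c0 - half_amp), rms_residual=rms,
                          low_signal=bool(low))


def stack_orientations(stack: np.ndarray, angles_deg: np.ndarray,
                       region_area_px2: float = 100.0, spacing_px: int = 20
                       ) -> pd.DataFrame:
    """Region grid + per-region orientation fits for a polarizer stack."""
    regions = region_grid(stack.shape[1:], region_area_px2, spacing_px)
    means = region_means(stack, regions)
    rows = []
    for j, (rs, cs) in enumerate(regions):
        fit = fit_region_orientation(means[:, j], angles_deg)
        rows.append({"region": j,
                     "row": (rs.start + rs.stop) // 2,
                     "col": (cs.start + cs.stop) // 2,
                     "theta_deg": fit.theta_deg, "amplitude": fit.amplitude,
                     "offset": fit.offset, "low_signal": fit.low_signal})
    return pd.DataFrame(rows)


def circular_stats(angles_deg, period_deg: float = 180.0) -> CircularStats:
    """Circular mean and SD of axial angles with the given period.

    Angles are scaled onto the full circle by k = 360/period; the resultant
    length Rbar gives CSD = sqrt(-2 ln Rbar)/k (converted to degrees).  CSD
    is invariant to adding a constant and to relabeling modulo the period.
    An (anti)parallel cancellation (Rbar = 0) is flagged degenerate with
    infinite CSD.
    """
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 2:
        raise ValueError("need >= 2 angles")
    k = 360.0 / period_deg
    z = np.exp(1j * np.radians(a * k))
    zbar = z.mean()
    rbar = float(np.abs(zbar))
    mean = float((np.degrees(np.angle(zbar)) / k) % period_deg)
    if mean > period_deg / 2:
        mean -= period_deg
    if rbar < 1e-12:
        return CircularStats(mean_deg=np.nan, csd_deg=np.inf,
                             period_deg=period_deg, n=a.size,
                             resultant_length=rbar, degenerate=True)
    csd = float(np.degrees(np.sqrt(-2.0 * np.log(rbar))) / k)
    return CircularStats(mean_deg=mean, csd_deg=csd, period_deg=period_deg,
                         n=a.size, resultant_length=rbar)


def realignment_transition(strain_pct, csd_deg, min_points: int = 5,
                           flat_tol: float = 0.02) -> BilinearFit:
    """Breakpoint of a continuous two-segment fit to CSD vs strain.

    The transition strain marks the onset of collagen fiber re-alignment.
    For each candidate breakpoint b the model
    csd = c + s1*strain + (s2 - s1)*max(strain - b, 0) is linear; the SSE is
    minimized by exhaustive search over an interior grid followed by
    golden-section refinement.  Data fitted (essentially) as well by a single
    line are flagged degenerate (transition undefined).
    """
    x = np.asarray(strain_pct, dtype=float)
    y = np.asarray(csd_deg, dtype=float)
    if x.size < min_points:
        raise ValueError(f"need >= {min_points} strain points")
    order = np.argsort(x)
    x, y = x[order], y[order]

    def sse_at(b):
        X = np.column_stack([np.ones_like(x), x, np.maximum(x - b, 0.0)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), beta

    # single-line reference
    X1 = np.column_stack([np.ones_like(x), x])
    b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    sse_line = float(np.sum((y - X1 @ b1) ** 2))
    var_y = float(np.sum((y - y.mean()) ** 2))

    lo, hi = x[1], x[-2]
    grid = np.linspace(lo, hi, 101)
    sses = [sse_at(b)[0] for b in grid]
    i0 = int(np.argmin(sses))
    blo = grid[max(i0 - 1, 0)]
    bhi = grid[min(i0 + 1, len(grid) - 1)]
    b_opt = optimize.minimize_scalar(lambda b: sse_at(b)[0],
                                     bounds=(blo, bhi), method="bounded",
                                     options={"xatol": 1e-10}).x
    sse, beta = sse_at(b_opt)
    slope_low, slope_high = beta[1], beta[1] + beta[2]
    degenerate = (var_y <= 1e-12
                  or (sse_line - sse) <= flat_tol * max(sse_line, 1e-300)
                  and abs(beta[2]) <= 1e-8 * (abs(beta[1]) + 1e-12))
    if var_y > 1e-12 and sse_line <= sse + 1e-12 * var_y:
        degenerate = True  # bilinear adds nothing: single line
    return BilinearFit(transition=float(b_opt), slope_low=float(slope_low),
                       slope_high=float(slope_high), intercept=float(beta[0]),
                       sse=sse, degenerate=bool(degenerate))


# ---------------------------------------------------------------------------
# SHG orientation by spectral second moments

def _window_orientation(win: np.ndarray) -> tuple[float, float]:
    """Dominant axial orientation (deg) and anisotropic energy of one window."""
    w = win - win.mean()
    n = win.shape[0]
    taper = np.hanning(n)
    w = w * taper[:, None] * taper[None, :]
    P = np.abs(np.fft.fftshift(np.fft.fft2(w))) ** 2
    c = n // 2
    ky, kx = np.mgrid[0:n, 0:n]
    ky = ky - c
    kx = kx - c
    P[c, c] = 0.0
    # annulus mask: the square k-domain (corners reach sqrt(2) k_max along
    # the diagonals) otherwise biases second moments toward the axes
    rr = np.hypot(kx, ky)
    P = np.where((rr >= 2.0) & (rr <= 0.6 * c), P, 0.0)
    tot = P.sum()
    if tot <= 0:
        return np.nan, 0.0
    # orientation tensor of spectral energy; note image rows grow downward,
    # so ky -> -ky converts to mathematical (ccw from +x) angles
    kym = -ky
    mxx = (P * kx * kx).sum() / tot
    myy = (P * kym * kym).sum() / tot
    mxy = (P * kx * kym).sum() / tot
    # principal axis of spectral energy; fibers run perpendicular to it
    ang_spec = 0.5 * np.degrees(np.arctan2(2 * mxy, mxx - myy))
    fiber = ang_spec + 90.0
    fiber = ((fiber + 90.0) % 180.0) - 90.0
    # anisotropy magnitude as energy-weighted eccentricity
    aniso = np.hypot(mxx - myy, 2 * mxy) / (mxx + myy)
    return float(fiber), float(aniso * tot)


def shg_orientation(image: np.ndarray, window: int = 64, step: int | None = None,
                    energy_floor: float = 0.05,
                    hist_bins: int = 36) -> tuple[pd.DataFrame, np.ndarray,
                                                  CircularStats]:
    """Per-window dominant fiber orientation from the Fourier power spectrum.

    Returns (table, histogram, stats): a per-window table with angles (deg,
    period 180) and anisotropy, the normalized angle histogram over
    ``hist_bins`` bins on (-90, 90], and the CSD over unmasked windows.
    Windows with anisotropic spectral energy below ``energy_floor`` of the
    maximum are masked.
    """
    H, W = image.shape
    if H < window or W < window:
        raise ValueError("image smaller than the analysis window")
    step = step or window // 2
    rows = []
    for r in range(0, H - window + 1, step):
        for c in range(0, W - window + 1, step):
            ang, energy = _window_orientation(image[r:r + window, c:c + window])
            rows.append({"row": r + window // 2, "col": c + window // 2,
                         "theta_deg": ang, "energy": energy})
    df = pd.DataFrame(rows)
    emax = df["energy"].max()
    df["masked"] = ~(df["energy"] > energy_floor * max(emax, 1e-300)) \
        | ~np.isfinite(df["theta_deg"])
    good = df.loc[~df["masked"], "theta_deg"].to_numpy()
    edges = np.linspace(-90.0, 90.0, hist_bins + 1)
    hist, _ = np.histogram(good, bins=edges, density=True)
    stats = circular_stats(good, period_deg=180.0) if good.size >= 2 else \
        CircularStats(np.nan, np.inf, 180.0, good.size, 0.0, True)
    return df, hist, stats


# ---------------------------------------------------------------------------
# nuclei and F-actin

def segment_nuclei(image: np.ndarray, threshold: str | float = "otsu",
                   min_area_px: int = 20) -> tuple[pd.DataFrame, CircularStats]:
    """Threshold + connected components -> per-nucleus shape table and nCSD.

    Accepts a fluorescence image (thresholded globally; Otsu by default) or
    an already-labeled integer image.  Each component's second-moment ellipse
    gives major/minor axes and orientation (deg, ccw from the +x image axis);
    nAR = major/minor.  nCSD is the circular SD (period 180) of orientations.
    """
    if np.issubdtype(image.dtype, np.integer) and image.max() > 1 and \
            len(np.unique(image)) > 2:
        labels = image
    else:
        if threshold == "otsu":
            thr = filters.threshold_otsu(image)
        else:
            thr = float(threshold)
        labels = measure.label(image > thr)
    props = measure.regionprops(labels)
    rows = []
    for p in props:
        if p.area < min_area_px or p.axis_minor_length <= 0:
            continue
        # regionprops orientation is measured from the row axis in (row, col)
        # coordinates; map to ccw-from-+x with y upward
        ang = ((90.0 + np.degrees(p.orientation)) % 180.0)
        if ang > 90.0:
            ang -= 180.0
        rows.append({"label": p.label,
                     "major_px": p.axis_major_length,
                     "minor_px": p.axis_minor_length,
                     "orientation_deg": ang,
                     "nAR": p.axis_major_length / p.axis_minor_length,
                     "area_px": p.area,
                     "cy": p.centroid[0], "cx": p.centroid[1]})
    df = pd.DataFrame(rows)
    if df.empty:
        warnings.warn("no nuclei found after filtering")
        return df, CircularStats(np.nan, np.inf, 180.0, 0, 0.0, True)
    stats = circular_stats(df["orientation_deg"], period_deg=180.0) \
        if len(df) >= 2 else CircularStats(float(df["orientation_deg"].iloc[0]),
                                           0.0, 180.0, 1, 1.0)
    return df, stats


def factin_fraction(image: np.ndarray, roi_mask: np.ndarray | None = None,
                    stretch_percentiles=(2.0, 98.0)) -> float:
    """Percent F-actin-positive pixels in the ROI after contrast stretch + Otsu."""
    if roi_mask is None:
        roi_mask = np.ones(image.shape, dtype=bool)
    if not np.any(roi_mask):
        raise ValueError("empty ROI")
    vals = image[roi_mask].astype(float)
    if np.ptp(vals) == 0:
        return 0.0 if vals.max() <= 0 else 100.0
    p_lo, p_hi = np.percentile(vals, stretch_percentiles)
    if p_hi > p_lo:
        vals = exposure.rescale_intensity(vals, in_range=(p_lo, p_hi))
    thr = filters.threshold_otsu(vals)
    return float(100.0 * np.mean(vals > thr))
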