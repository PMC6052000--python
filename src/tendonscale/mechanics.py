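"""Per-cycle and per-strain-level tensile metrics from force-displacement records.

Processes labeled time series from cyclic tendon tests: per-cycle extrema,
tangent stiffness, dynamic modulus and hysteresis; laxity accumulation over
fatigue cycles; dynamic modulus |E*| and loss tangent tan(delta) from
sinusoidal frequency sweeps; and equilibrium stress after stress-relaxation
holds (whose change between 1% and 10% strain indexes strain stiffening).
Stress is force over cross-sectional area (MPa with N and mm^2); strain is
displacement over gauge length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class UndersampledError(ValueError):
    """Fewer than 2 samples per quarter cycle."""


class DegenerateCycleError(ValueError):
    """Cycle with zero displacement range."""


class MissingSegmentError(KeyError):
    """Requested labeled segment absent from the record."""


@dataclass
class ForceDisplacementRecord:
    """Synchronized time / displacement / force series with specimen geometry.

    ``segment_labels`` assigns each sample to a protocol phase such as
    ``precondition``, ``cyclic``, ``ramp_1`` / ``ramp_10``, ``hold_1`` /
    ``hold_10``, ``sweep_<freq>``, ``recovery``.
    """

    time: np.ndarray
    displacement: np.ndarray
    force: np.ndarray
    gauge_length: float
    cross_sectional_area: float
    segment_labels: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.segment_labels = np.asarray(self.segment_labels)
        if not (len(self.time) == len(self.displacement) == len(self.force)
                == len(self.segment_labels)):
            raise ValueError("series lengths differ")
        if np.any(np.diff(self.time) < 0):
            raise ValueError("time must be monotone nondecreasing")
        if self.gauge_length <= 0 or self.cross_sectional_area <= 0:
            raise ValueError("gauge length and area must be > 0")

    @property
    def stress(self) -> np.ndarray:
        """MPa (N / mm^2)."""
        return self.force / self.cross_sectional_area

    @property
    def strain(self) -> np.ndarray:
        """Dimensionless (mm / mm)."""
        return self.displacement / self.gauge_length

    def segment(self, label: str) -> np.ndarray:
        mask = self.segment_labels == label
        if not np.any(mask):
            raise MissingSegmentError(
                f"no samples labeled {label!r}; present: "
                f"{sorted(set(self.segment_labels.tolist()))}")
        return mask

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "time_s": self.time, "displacement_mm": self.displacement,
            "force_N": self.force, "segment": self.segment_labels,
        }).to_csv(path, index=False)
        meta = Path(str(path)).with_suffix(".meta.csv")
        pd.DataFrame({"gauge_length_mm": [self.gauge_length],
                      "area_mm2": [self.cross_sectional_area]}).to_csv(
            meta, index=False)

    @classmethod
    def from_csv(cls, path, gauge_length: float | None = None,
                 cross_sectional_area: float | None = None
                 ) -> "ForceDisplacementRecord":
        df = pd.read_csv(path)
        if gauge_length is None or cross_sectional_area is None:
            meta = pd.read_csv(Path(str(path)).with_suffix(".meta.csv"))
            gauge_length = float(meta["gauge_length_mm"].iloc[0])
            cross_sectional_area = float(meta["area_mm2"].iloc[0])
        return cls(df["time_s"].to_numpy(), df["displacement_mm"].to_numpy(),
                   df["force_N"].to_numpy(), gauge_length, cross_sectional_area,
                   df["segment"].to_numpy())


@dataclass
class CyclicMechanicsSummary:
    per_cycle: pd.DataFrame            # one row per detected cycle
    sweep: pd.DataFrame | None = None  # one row per sweep frequency
    s_eq: dict[float, float] = field(default_factory=dict)   # strain % -> MPa
    delta_s_eq: float | None = None
    delta_s_eq_percent: float | None = None


def _loop_area(x: np.ndarray, y: np.ndarray) -> float:
    """Signed shoelace area of the closed (x, y) loop; positive = clockwise."""
    x2 = np.append(x, x[0])
    y2 = np.append(y, y[0])
    return -0.5 * float(np.sum(x2[:-1] * y2[1:] - x2[1:] * y2[:-1]))


def detect_cycles(time: np.ndarray, signal: np.ndarray,
                  frequency: float) -> list[np.ndarray]:
    """Split an oscillatory segment into cycles at the protocol frequency.

    Uses rising zero-crossings of the linearly detrended signal; cycles
    shorter than half the nominal period are discarded as crossing noise.
    """
    dt = np.median(np.diff(time))
    if dt * 4.0 * frequency > 1.0 / 2.0:
        raise UndersampledError(
            f"~{1.0 / (dt * frequency):.1f} samples/cycle; need >= 8")
    coeff = np.polyfit(time, signal, 1)
    det = signal - np.polyval(coeff, time)
    rising = np.flatnonzero((det[:-1] < 0) & (det[1:] >= 0)) + 1
    bounds = [i for i in rising]
    cycles = []
    min_len = 0.5 / frequency
    start = bounds[0] if bounds else 0
    for end in bounds[1:]:
        if time[end] - time[start] >= min_len:
            cycles.append(np.arange(start, end))
            start = end
    return cycles


def cycle_metrics(record: ForceDisplacementRecord, frequency: float = 1.0,
                  segment: str = "cyclic") -> CyclicMechanicsSummary:
    """Per-cycle extrema, stiffness, dynamic modulus, hysteresis, and laxity.

    Laxity of cycle i is (d_peak,i - d_peak,1) / gauge_length (zero for the
    first cycle by definition); hysteresis is the enclosed stress-strain loop
    area (MPa), positive for dissipative clockwise loops.
    """
    mask = record.segment(segment)
    t = record.time[mask]
    d = record.displacement[mask]
    f = record.force[mask]
    cycles = detect_cycles(t, d, frequency)
    if not cycles:
        raise ValueError("no complete cycles detected")

    area = record.cross_sectional_area
    gl = record.gauge_length
    rows = []
    d_peak_1 = None
    for i, idx in enumerate(cycles):
        dc, fc = d[idx], f[idx]
        d_rng = dc.max() - dc.min()
        if d_rng <= 1e-12 * max(1.0, np.abs(dc).max()):
            raise DegenerateCycleError(f"cycle {i + 1} has zero displacement range")
        strain = dc / gl
        stress = fc / area
        d_peak = dc.max()
        if d_peak_1 is None:
            d_peak_1 = d_peak
        rows.append({
            "cycle": i + 1,
            "d_max_mm": dc.max(), "d_min_mm": dc.min(),
            "strain_max_pct": strain.max() * 100, "strain_min_pct": strain.min() * 100,
            "tangent_stiffness_N_mm": (fc.max() - fc.min()) / d_rng,
            "dynamic_modulus_MPa": (stress.max() - stress.min())
                                   / (strain.max() - strain.min()),
            "hysteresis_MPa": _loop_area(strain, stress),
            "laxity": (d_peak - d_peak_1) / gl,
        })
    return CyclicMechanicsSummary(per_cycle=pd.DataFrame(rows))


def _fit_sinusoid(t: np.ndarray, y: np.ndarray, freq: float) -> tuple[float, float]:
    """Least-squares amplitude and phase of y ~ amp*sin(2 pi f t + phase) + c."""
    w = 2.0 * np.pi * freq
    X = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b = beta[0], beta[1]
    amp = float(np.hypot(a, b))
    if amp < 1e-14 * (np.abs(y).max() + 1e-300):
        raise RuntimeError("sinusoid fit degenerate: zero amplitude")
    return amp, float(np.arctan2(b, a))


def frequency_sweep_metrics(record: ForceDisplacementRecord, frequencies,
                            strain_level: float | None = None) -> pd.DataFrame:
    """|E*| (MPa) and tan(delta) per sweep frequency.

    Each sweep segment (``sweep_<f>`` or ``sweep_<f>@<strain>`` when sweeps
    were run at multiple strain levels) gets an independent sinusoid fit to
    stress and strain; |E*| is the stress/strain amplitude ratio and
    tan(delta) the tangent of the stress-strain phase lag, wrapped to
    [0, pi/2).  With several strain levels present and none requested, the
    highest is used.
    """
    rows = []
    labels_present = set(record.segment_labels.tolist())
    for freq in frequencies:
        if strain_level is not None:
            label = f"sweep_{freq:g}@{strain_level:g}"
        elif f"sweep_{freq:g}" in labels_present:
            label = f"sweep_{freq:g}"
        else:
            lv = [float(s.split("@")[1]) for s in labels_present
                  if str(s).startswith(f"sweep_{freq:g}@")]
            if not lv:
                raise MissingSegmentError(f"no sweep segment at {freq:g} Hz")
            label = f"sweep_{freq:g}@{max(lv):g}"
        mask = record.segment(label)
        t = record.time[mask]
        s_amp, s_ph = _fit_sinusoid(t, record.stress[mask], freq)
        e_amp, e_ph = _fit_sinusoid(t, record.strain[mask], freq)
        lag = (s_ph - e_ph) % np.pi
        if lag >= np.pi / 2.0:
            lag -= np.pi  # wrap into (-pi/2, pi/2); dissipative lags are >= 0
        lag = abs(lag)
        rows.append({"frequency_Hz": freq, "E_star_MPa": s_amp / e_amp,
                     "tan_delta": float(np.tan(lag)), "phase_lag_rad": lag})
    return pd.DataFrame(rows)


def equilibrium_stress(record: ForceDisplacementRecord, strain_level: float,
                       window_fraction: float = 0.10) -> float:
    """Mean stress (MPa) over the final ``window_fraction`` of the hold segment
    at ``strain_level`` (percent strain; segment label ``hold_<level>``)."""
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must lie in (0, 1]")
    mask = record.segment(f"hold_{strain_level:g}")
    t = record.time[mask]
    s = record.stress[mask]
    t0 = t[-1] - window_fraction * (t[-1] - t[0])
    return float(np.mean(s[t >= t0]))


def strain_stiffening(record: ForceDisplacementRecord,
                      low: float = 1.0, high: float = 10.0,
                      window_fraction: float = 0.10) -> CyclicMechanicsSummary:
    """Equilibrium stresses at both strain levels and their change.

    Delta s_eq = s_eq(high) - s_eq(low) is reported both absolute (MPa) and
    as percent of s_eq(low).
    """
    s_lo = equilibrium_stress(record, low, window_fraction)
    s_hi = equilibrium_stress(record, high, window_fraction)
    return CyclicMechanicsSummary(
        per_cycle=pd.DataFrame(),
        s_eq={low: s_lo, high: s_hi},
        delta_s_eq=s_hi - s_lo,
        delta_s_eq_percent=(100.0 * (s_hi - s_lo) / s_lo if s_lo != 0 else np.nan))
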