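"""Structurally based elastic model of collagen fiber recruitment.

Tendon's nonlinear toe region arises from crimped fibers that only begin to
bear load once the tissue is stretched past their individual slack lengths.
The model treats the slack-length population as Gaussian with mean ``mu`` and
standard deviation ``sigma`` (both mm); each recruited fiber is a linear
spring of stiffness ``K_avg`` (N/mm).  Summing (or taking the expectation
over) the population gives a force-displacement curve with a smooth toe that
straightens to slope ``K_tot = K_avg * N_fibers`` once essentially every
fiber is engaged.  Disorganized tissue maps onto large ``mu`` and ``sigma``
(an elongated toe); fatigue damage maps onto an increase in ``mu``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


class ExtrapolationWarning(UserWarning):
    """Fitted recruitment parameters extend beyond the sampled displacement range."""


@dataclass(frozen=True)
class RecruitmentParams:
    """Gaussian slack-length population and fiber stiffness.

    Attributes
    ----------
    mu : float
        Mean fiber slack length, mm.
    sigma : float
        Standard deviation of slack lengths, mm (>= 0).
    K_avg : float
        Average single-fiber stiffness, N/mm.
    N_fibers : int
        Number of fibers in the population (discrete mode).
    """

    mu: float
    sigma: float
    K_avg: float = 1.0
    N_fibers: int = 1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.K_avg <= 0:
            raise ValueError("K_avg must be > 0")
        if self.N_fibers < 1:
            raise ValueError("N_fibers must be >= 1")

    @property
    def K_tot(self) -> float:
        """Total recruited stiffness K_avg * N_fibers, N/mm."""
        return self.K_avg * self.N_fibers

    @classmethod
    def from_total_stiffness(cls, mu: float, sigma: float, K_tot: float,
                             N_fibers: int = 1) -> "RecruitmentParams":
        return cls(mu=mu, sigma=sigma, K_avg=K_tot / N_fibers, N_fibers=N_fibers)


@dataclass
class RecruitmentFit:
    """Result of fitting the expectation-mode force model to an (x, F) curve."""

    params: RecruitmentParams
    cov: np.ndarray              # covariance of (mu, log sigma, log K_tot)
    ci: dict[str, tuple[float, float]]
    residuals: np.ndarray
    rmse: float
    slack_strain: float | None   # mu / gauge_length when gauge length known
    extrapolated: bool


def recruitment_cdf(L0, params: RecruitmentParams):
    """Cumulative probability that a fiber with slack length <= ``L0`` is uncrimped.

    The Gaussian CDF Phi((L0 - mu)/sigma).  For sigma == 0 the population is
    degenerate and the step branch 0 / 0.5 / 1 is returned.
    """
    L0 = np.asarray(L0, dtype=float)
    if params.sigma == 0.0:
        out = np.where(L0 > params.mu, 1.0, np.where(L0 < params.mu, 0.0, 0.5))
        return out if out.ndim else float(out)
    p = stats.norm.cdf(L0, loc=params.mu, scale=params.sigma)
    return p if np.ndim(p) else float(p)


def recruitment_force(x, params: RecruitmentParams, mode: str = "expectation",
                      rng: np.random.Generator | None = None,
                      slack_lengths: np.ndarray | None = None):
    """Force carried by the fiber population at tendon displacement ``x`` (mm).

    ``expectation`` mode evaluates the population expectation of
    K_avg * sum_i (x - L0_i) H(x - L0_i):

        F(x) = K_tot * [ (x - mu) Phi(z) + sigma phi(z) ],   z = (x - mu)/sigma

    which is nonnegative, nondecreasing, and convex in x, with slope -> K_tot
    as x -> inf.  ``discrete`` mode draws (or is given) ``N_fibers`` slack
    lengths and sums the Heaviside-gated spring forces directly.
    """
    x = np.asarray(x, dtype=float)
    if mode == "expectation":
        if params.sigma == 0.0:
            F = params.K_tot * np.maximum(x - params.mu, 0.0)
        else:
            z = (x - params.mu) / params.sigma
            F = params.K_tot * ((x - params.mu) * stats.norm.cdf(z)
                                + params.sigma * stats.norm.pdf(z))
        return F if F.ndim else float(F)
    if mode == "discrete":
        if slack_lengths is None:
            if rng is None:
                rng = np.random.default_rng()
            slack_lengths = rng.normal(params.mu, params.sigma, params.N_fibers)
        stretch = x[..., None] - slack_lengths
        F = params.K_avg * np.where(stretch > 0.0, stretch, 0.0).sum(axis=-1)
        return F if np.ndim(F) else float(F)
    raise ValueError(f"unknown mode {mode!r}")


def _model(x, mu, log_sigma, log_ktot):
    p = RecruitmentParams.from_total_stiffness(mu, np.exp(log_sigma), np.exp(log_ktot))
    return recruitment_force(x, p)


def fit_recruitment(x, force, gauge_length: float | None = None,
                    n_starts: int = 5) -> RecruitmentFit:
    """Fit (mu, sigma, K_tot) by nonlinear least squares of the expectation model.

    Parameterized internally as (mu, log sigma, log K_tot) for positivity.
    Deterministic multistart: ``n_starts`` initial mu values spanning the
    displacement range; sigma starts at 10% of the range and K_tot at the
    upper-end secant slope.  An :class:`ExtrapolationWarning` is raised when
    max(x) < mu + 2 sigma post hoc (linear region not reached by the data).
    """
    x = np.asarray(x, dtype=float)
    force = np.asarray(force, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    span = x.max() - x.min()
    if span <= 0:
        raise ValueError("displacement range is degenerate")

    # secant slope over the stiffest (upper) quarter of the curve -> K_tot guess
    hi = x >= x.max() - 0.25 * span
    k_guess = max(np.polyfit(x[hi], force[hi], 1)[0], 1e-8) if hi.sum() >= 2 else \
        max(force.max() / span, 1e-8)

    best = None
    for frac in np.linspace(0.1, 0.9, n_starts):
        theta0 = (x.min() + frac * span, np.log(0.1 * span), np.log(k_guess))
        try:
            res = optimize.least_squares(
                lambda th: _model(x, *th) - force, theta0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("recruitment fit failed to converge from all starts")

    mu, log_sigma, log_ktot = best.x
    sigma, ktot = np.exp(log_sigma), np.exp(log_ktot)
    params = RecruitmentParams.from_total_stiffness(mu, sigma, ktot)

    # Gauss-Newton covariance in the internal parameterization
    J = best.jac
    dof = max(x.size - 3, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov = np.full((3, 3), np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    tcrit = stats.t.ppf(0.975, dof)
    ci = {
        "mu": (mu - tcrit * se[0], mu + tcrit * se[0]),
        "sigma": (sigma * np.exp(-tcrit * se[1]), sigma * np.exp(tcrit * se[1])),
        "K_tot": (ktot * np.exp(-tcrit * se[2]), ktot * np.exp(tcrit * se[2])),
    }

    # linear region unsampled (tail beyond the data) or toe unsampled
    # (recruitment essentially complete before the first sample)
    extrapolated = bool(x.max() < mu + 2.0 * sigma
                        or x.min() > mu + 2.0 * sigma)
    if extrapolated:
        warnings.warn(
            f"fitted recruitment band mu +/- 2 sigma = "
            f"[{mu - 2 * sigma:.4g}, {mu + 2 * sigma:.4g}] not bracketed by the "
            f"sampled displacement range [{x.min():.4g}, {x.max():.4g}]",
            ExtrapolationWarning)

    resid = _model(x, *best.x) - force
    return RecruitmentFit(
        params=params, cov=cov, ci=ci, residuals=resid,
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        slack_strain=(mu / gauge_length if gauge_length else None),
        extrapolated=extrapolated)
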