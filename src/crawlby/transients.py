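"""Transient-time observation and the analytic crawl-by / ghost approximations.

Three long-transient regimes of the pulse map are quantified here:

* **Resource-extinction crawl-by** -- a large initial consumer density
  ``p0 ~ 1/eps`` crashes the resource, which then hovers near zero until
  the consumer has decayed; recovery begins after roughly
  ``log(eps) / log(delta_p)`` pulses.
* **Carrying-capacity crawl-by** -- above the bifurcation
  (``gamma_p > gamma_p*``) a rare consumer ``p0 = eps`` invades at rate
  ``lambda_1 > 1`` while the resource sits near ``n*``; the resource
  starts its collapse after roughly ``log(1/eps) / log(lambda_1)`` pulses.
* **Ghost limit cycle** -- just below the bifurcation
  (``eps = gamma_p* - gamma_p`` small) the vanished consumer-resource
  cycle persists as a ghost; the escape time
  ``tau = min{M : n_M > n_hat, p_M < p_hat}`` (with ``(p_hat, n_hat)``
  the upper coexistence state) is summarised by the power law
  ``tau = A * eps**-B`` fitted in log-log coordinates.

Observed times are read off simulated trajectories in log space.  The
observed start of resource recovery is the first strict increase of the
resource series.  The observed escape from the carrying-capacity crawl-by
defaults to the first crossing below half the carrying capacity: the
consumer's mere presence depresses recruitment by ``O(eps)`` from the very
first pulse, so a first-strict-decrease reading degenerates to 1 for every
``eps``; a direction-based mode is still available via ``mode=``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .equilibria import (
    LABEL_COEXISTENCE_HIGH,
    EquilibriumCatalog,
    bifurcation_value,
    carrying_capacity,
    catalog,
    lambda1,
)
from .model import ParamSet, ParameterError, State, Trajectory, simulate

__all__ = [
    "TransientEstimate",
    "PowerLawFit",
    "recovery_time_observed",
    "recovery_time_estimate",
    "escape_time_observed",
    "escape_time_estimate",
    "ghost_escape_time",
    "monotone_after",
    "tau_sweep",
    "default_epsilon_grid",
    "fit_power_law",
    "scaling_slope",
]

logger = logging.getLogger(__name__)

#: log-space tolerance under which consecutive states count as tied
DIRECTION_TOL = 1e-12


@dataclass(frozen=True)
class TransientEstimate:
    """An observed transient time paired with its analytic approximation.

    ``epsilon`` records the small parameter of the relevant regime:
    ``1/p0`` for the extinction crawl-by, ``p0`` for the
    carrying-capacity crawl-by, ``gamma_p* - gamma_p`` for the ghost.
    ``observed_time`` is ``None`` when the event was not reached within
    the simulated horizon.
    """

    observed_time: Optional[int]
    estimated_time: float
    epsilon: float
    kind: str  # extinction_crawlby | carrying_capacity_crawlby | ghost_escape

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ParameterError(f"epsilon must be > 0, got {self.epsilon!r}")
        if self.observed_time is not None and self.observed_time < 0:
            raise ParameterError("observed_time must be >= 0 when reached")


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares power law ``tau = A * epsilon**-B`` in log-log space."""

    A: float
    B: float
    r_squared: float
    sample: tuple[tuple[float, float], ...]
    gamma_p_star: Optional[float] = None

    def predict(self, epsilon: float) -> float:
        return self.A * epsilon ** (-self.B)


def _checked_log_n(traj: Trajectory) -> np.ndarray:
    ln = traj.log_n
    if len(ln) < 2:
        raise ValueError("trajectory must contain at least 2 states")
    if np.any(np.isneginf(ln)):
        raise ParameterError("resource is extinct somewhere on the trajectory; transient time undefined")
    return ln


def recovery_time_observed(traj: Trajectory, *, mode: str = "direction",
                           threshold: Optional[float] = None,
                           tol: float = DIRECTION_TOL) -> Optional[int]:
    """First pulse at which the resource series turns upward.

    Default (``mode="direction"``): ``min{m >= 1 : n_m > n_{m-1}}``, with
    comparisons in log space and ties within ``tol`` counting as no
    change.  ``mode="threshold"`` instead returns the first pulse with
    ``n_m > threshold`` (absolute density).  Returns ``None`` when the
    event does not occur within the horizon.
    """
    ln = _checked_log_n(traj)
    if mode == "direction":
        idx = np.nonzero(np.diff(ln) > tol)[0]
    elif mode == "threshold":
        if threshold is None or threshold <= 0:
            raise ValueError("threshold mode requires a positive threshold density")
        idx = np.nonzero(ln[1:] > math.log(threshold))[0]
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'direction' or 'threshold'")
    return int(idx[0] + 1) if len(idx) else None


def recovery_time_estimate(params: ParamSet, p0: float) -> float:
    """Analytic crawl-by estimate ``log(p0) / (-log(delta_p))``.

    Valid for a large initial consumer density ``p0 = 1/eps > 1``: the
    resource stays suppressed while the consumer decays geometrically at
    rate ``delta_p``, and recovery begins once the consumer is O(1).
    """
    if p0 <= 1.0:
        raise ParameterError(f"recovery estimate requires p0 > 1 (eps = 1/p0 < 1), got {p0!r}")
    return math.log(p0) / (-math.log(params.delta_p))


def escape_time_observed(traj: Trajectory, *, mode: str = "threshold",
                         threshold: Optional[float] = None,
                         tol: float = DIRECTION_TOL) -> Optional[int]:
    """First pulse at which the resource has measurably started collapsing.

    Default (``mode="threshold"``): first ``m >= 1`` with ``n_m`` below
    half the carrying capacity (or below ``threshold`` if given).  The
    consumer depresses recruitment by ``O(eps)`` from the first pulse, so
    the alternative ``mode="direction"`` (first strict decrease of the
    resource series) fires immediately for any starting perturbation and
    is kept only for completeness.
    """
    ln = _checked_log_n(traj)
    if mode == "threshold":
        thr = threshold if threshold is not None else 0.5 * carrying_capacity(traj.params)
        if thr <= 0:
            raise ValueError("threshold must be positive")
        idx = np.nonzero(ln[1:] < math.log(thr))[0]
    elif mode == "direction":
        idx = np.nonzero(np.diff(ln) < -tol)[0]
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'threshold' or 'direction'")
    return int(idx[0] + 1) if len(idx) else None


def escape_time_estimate(params: ParamSet, epsilon: float) -> float:
    """Analytic crawl-by estimate ``log(1/eps) / log(lambda_1)``.

    Valid above the bifurcation, where a rare consumer ``p0 = eps`` grows
    at rate ``lambda_1 > 1`` near the carrying capacity; diverges as
    ``gamma_p`` approaches the bifurcation from above.
    """
    if not 0.0 < epsilon < 1.0:
        raise ParameterError(f"escape estimate requires 0 < epsilon < 1, got {epsilon!r}")
    lam = lambda1(params)
    if lam <= 1.0:
        raise ParameterError(
            f"escape estimate requires gamma_p > gamma_p* (lambda_1 > 1), got lambda_1 = {lam!r}"
        )
    return math.log(1.0 / epsilon) / math.log(lam)


def ghost_escape_time(traj: Trajectory, cat: EquilibriumCatalog) -> Optional[int]:
    """First pulse inside the monotone-recovery basin past the upper saddle.

    ``tau = min{M : n_M > n_hat, p_M < p_hat}`` where ``(p_hat, n_hat)``
    is the upper coexistence saddle.  From that pulse on the resource
    increases and the consumer decreases monotonically (see
    :func:`monotone_after`).  Returns ``None`` if the basin is not
    entered within the horizon.
    """
    upper = cat.get(LABEL_COEXISTENCE_HIGH)
    if upper is None:
        raise ParameterError(
            "escape criterion undefined: no upper coexistence equilibrium in catalog "
            "(requires gamma_p < gamma_p* with positive discriminant)"
        )
    lp_hat = math.log(upper.location.p)
    ln_hat = math.log(upper.location.n)
    cond = (traj.log_n > ln_hat) & (traj.log_p < lp_hat)
    idx = np.nonzero(cond)[0]
    return int(idx[0]) if len(idx) else None


def monotone_after(traj: Trajectory, m: int, tol: float = DIRECTION_TOL) -> bool:
    """Whether resource rises and consumer falls from pulse ``m`` onward.

    Checked in log space; steps smaller than ``tol`` count as ties (the
    approach to equilibrium eventually stalls at machine precision).
    """
    dn = np.diff(traj.log_n[m:])
    dp = np.diff(traj.log_p[m:])
    return bool(np.all(dn > -tol) and np.all(dp < tol))


def default_epsilon_grid(params: ParamSet, num: int = 12) -> np.ndarray:
    """Geometric grid of ``gamma_p* - gamma_p`` offsets spanning the ghost regime."""
    gps = bifurcation_value(params)
    return np.geomspace(1e-3 * gps, 1e-1 * gps, num)


def tau_sweep(params_base: ParamSet, epsilon_grid: Sequence[float],
              s0: State | tuple[float, float], horizon: int) -> list[tuple[float, int]]:
    """Ghost escape time for each bifurcation offset ``eps = gamma_p* - gamma_p``.

    For each offset the map is simulated from ``s0`` with
    ``gamma_p = gamma_p* - eps`` and the escape time recorded.  Offsets
    whose escape is not reached within ``horizon`` are dropped with a
    warning; raises if every entry is dropped.
    """
    gps = bifurcation_value(params_base)
    out: list[tuple[float, int]] = []
    for eps in epsilon_grid:
        if not 0.0 < eps < gps:
            raise ParameterError(f"epsilon must lie in (0, gamma_p* = {gps!r}), got {eps!r}")
        params = params_base.replace(gamma_p=gps - eps)
        cat = catalog(params)
        traj = simulate(s0, params, horizon)
        tau = ghost_escape_time(traj, cat)
        if tau is None:
            logger.warning("escape not reached within horizon %d at epsilon = %g; dropped", horizon, eps)
        else:
            out.append((float(eps), tau))
    if not out:
        raise RuntimeError(
            f"no escape observed within horizon {horizon} for any epsilon; increase the horizon"
        )
    return out


def fit_power_law(sample: Sequence[tuple[float, float]],
                  gamma_p_star: Optional[float] = None) -> PowerLawFit:
    """Ordinary least squares of ``log(tau)`` on ``log(epsilon)``.

    Returns ``A = exp(intercept)``, ``B = -slope`` and the r-squared of
    the log-log fit.  Requires at least 3 pairs with positive
    coordinates and non-degenerate epsilons.
    """
    if len(sample) < 3:
        raise ValueError(f"power-law fit requires >= 3 pairs, got {len(sample)}")
    eps = np.asarray([e for e, _ in sample], dtype=float)
    tau = np.asarray([t for _, t in sample], dtype=float)
    if np.any(eps <= 0) or np.any(tau <= 0):
        raise ValueError("all epsilon and tau values must be positive")
    x = np.log(eps)
    y = np.log(tau)
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all epsilon values equal")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = intercept + slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        A=float(np.exp(intercept)),
        B=float(-slope),
        r_squared=r2,
        sample=tuple((float(e), float(t)) for e, t in sample),
        gamma_p_star=gamma_p_star,
    )


def scaling_slope(times: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Least-squares slope and intercept of time against ``log(1/epsilon)``.

    ``times`` holds ``(log_epsilon, observed_time)`` pairs; used to test
    the crawl-by scalings, whose slopes should match
    ``1/(-log delta_p)`` and ``1/log(lambda_1)`` respectively.
    """
    if len(times) < 3:
        raise ValueError(f"scaling slope requires >= 3 pairs, got {len(times)}")
    x = np.asarray([-le for le, _ in times], dtype=float)  # log(1/epsilon)
    y = np.asarray([t for _, t in times], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
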