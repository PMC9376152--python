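"""Core discrete-time consumer-resource map with group defense and pulsed recruitment.

The model follows adult consumer density ``p`` and adult resource density
``n`` from one reproductive pulse to the next.  Between pulses both
populations decay exponentially and the consumer depresses the resource
through a unimodal (Type IV Holling) functional response ``n / (1 + sigma
n**2)`` that represents group defense: per-capita consumption risk peaks at
``n = 1 / sqrt(sigma)`` and *declines* at higher resource density.  At each
pulse, consumer recruitment is proportional to consumption, and resource
recruitment is Beverton-Holt limited and reduced by consumer predation on
offspring.

In nondimensional form the pulse-to-pulse map is::

    p' = delta_p * p + gamma_p * p * n / (1 + sigma * n**2)
    n' = delta_n * n * exp(-gamma_n * p / (1 + sigma * n**2))
         + R * n * exp(-p) / (1 + n)

with per-pulse survivals ``delta_p, delta_n`` in (0, 1), conversion
intensity ``gamma_p``, scaled attack rate ``gamma_n``, group-defense
strength ``sigma`` and per-capita recruit number ``R``.

Long transients in this map pass through states within a few hundred
log-units of zero, far outside double-precision range, so :func:`simulate`
iterates the exact logarithmic transform of the map by default.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParameterError",
    "MapOverflowError",
    "DimensionalParams",
    "ParamSet",
    "State",
    "Trajectory",
    "Finding",
    "ValidationReport",
    "nondimensionalize",
    "step",
    "step_resource_only",
    "log_step",
    "simulate",
    "validate_params",
]


class ParameterError(ValueError):
    """A parameter set or state violates a hard model constraint."""


class MapOverflowError(FloatingPointError):
    """Linear-space iteration left double-precision range.

    Long transients routinely visit densities like ``exp(-150)``; re-run
    the simulation with ``log_space=True`` (the default), which iterates
    the exact logarithmic transform of the map instead.
    """


def _require_positive(obj, fields: Sequence[str]) -> None:
    for name in fields:
        v = getattr(obj, name)
        if not (math.isfinite(v) and v > 0):
            raise ParameterError(f"{type(obj).__name__}.{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional parameters of the impulsive consumer-resource system.

    Continuous-time mortality rates ``d_p`` (consumer) and ``d_n``
    (resource) act between pulses; ``gamma_n`` is the consumer attack
    rate, ``sigma_n`` shapes the group-defense response (consumption
    peaks at resource density ``1/sqrt(sigma_n)``), ``gamma_p`` converts
    consumption into consumer recruits, ``1/gamma_s`` is the mean of the
    exponential offspring consumption-survival distribution, ``1/beta``
    scales the recruit carrying capacity and ``R`` is the per-capita
    number of resource recruits.

    ``R > 1 - exp(-d_n)`` is required so the resource replenishes itself
    in the absence of consumers.
    """

    d_p: float
    d_n: float
    gamma_n: float
    sigma_n: float
    gamma_p: float
    gamma_s: float
    beta: float
    R: float

    def __post_init__(self) -> None:
        _require_positive(self, ("d_p", "d_n", "gamma_n", "sigma_n", "gamma_p", "gamma_s", "beta", "R"))
        floor = 1.0 - math.exp(-self.d_n)
        if self.R <= floor:
            raise ParameterError(
                f"self-replenishment requires R > 1 - exp(-d_n) = {floor!r}, got R = {self.R!r}"
            )


@dataclass(frozen=True)
class ParamSet:
    """Nondimensional parameters of the pulse-to-pulse map.

    ``delta_p`` and ``delta_n`` are per-pulse survival fractions (strictly
    inside (0, 1)), ``gamma_p`` the consumer conversion intensity,
    ``gamma_n`` the scaled attack rate, ``sigma`` the group-defense
    strength and ``R`` the per-capita recruit number.

    ``sigma = 0`` is accepted as the degenerate no-group-defense limit
    (the functional response becomes linear in ``n``).  The soft
    conditions -- self-replenishment ``R > 1 - delta_n`` and group-defense
    relevance ``n* > 1/sqrt(sigma)`` -- are reported by
    :func:`validate_params` rather than enforced at construction, so that
    invalid regimes can be inspected; operations that require them raise.
    """

    delta_p: float
    delta_n: float
    gamma_p: float
    gamma_n: float
    sigma: float
    R: float

    def __post_init__(self) -> None:
        for name in ("delta_p", "delta_n"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 < v < 1.0):
                raise ParameterError(f"ParamSet.{name} must lie strictly inside (0, 1), got {v!r}")
        _require_positive(self, ("gamma_p", "gamma_n", "R"))
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise ParameterError(f"ParamSet.sigma must be finite and >= 0, got {self.sigma!r}")

    @property
    def self_replenishing(self) -> bool:
        """Whether the consumer-free resource persists (``R > 1 - delta_n``)."""
        return self.R > 1.0 - self.delta_n

    def replace(self, **kwargs) -> "ParamSet":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class State:
    """A pulse-time state ``(p, n)``; both densities finite and nonnegative."""

    p: float
    n: float

    def __post_init__(self) -> None:
        for name in ("p", "n"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ParameterError(f"State.{name} must be finite and >= 0, got {v!r}")

    def __iter__(self) -> Iterator[float]:
        yield self.p
        yield self.n


def nondimensionalize(dim: DimensionalParams) -> ParamSet:
    """Convert dimensional parameters to the nondimensional map parameters.

    Uses ``delta_p = exp(-d_p)``, ``delta_n = exp(-d_n)``,
    ``gamma_p = gamma_p/beta``, ``gamma_n = gamma_n*exp(-d_p)/gamma_s``,
    ``sigma = sigma_n/beta**2``; ``R`` is already dimensionless.  Under
    the state rescaling ``p = gamma_s*P``, ``n = beta*N`` one step of the
    dimensional map equals one step of the nondimensional map.
    """
    return ParamSet(
        delta_p=math.exp(-dim.d_p),
        delta_n=math.exp(-dim.d_n),
        gamma_p=dim.gamma_p / dim.beta,
        gamma_n=dim.gamma_n * math.exp(-dim.d_p) / dim.gamma_s,
        sigma=dim.sigma_n / dim.beta ** 2,
        R=dim.R,
    )


def step_dimensional(P: float, N: float, dim: DimensionalParams) -> tuple[float, float]:
    """One pulse of the dimensional map (used for equivalence checks)."""
    delta_p = math.exp(-dim.d_p)
    delta_n = math.exp(-dim.d_n)
    den = 1.0 + dim.sigma_n * N * N
    P1 = delta_p * P + dim.gamma_p * P * N / den
    N1 = (delta_n * N * math.exp(-dim.gamma_n * delta_p * P / den)
          + dim.R * N * math.exp(-dim.gamma_s * P) / (1.0 + dim.beta * N))
    return P1, N1


def step(s: State, params: ParamSet) -> State:
    """One pulse of the nondimensional map in linear space.

    Raises :class:`MapOverflowError` if the result leaves floating range;
    use log-space simulation for trajectories that approach the axes.
    """
    p, n = s.p, s.n
    den = 1.0 + params.sigma * n * n
    p1 = params.delta_p * p + params.gamma_p * p * n / den
    n1 = (params.delta_n * n * math.exp(-params.gamma_n * p / den)
          + params.R * n * math.exp(-p) / (1.0 + n))
    if not (math.isfinite(p1) and math.isfinite(n1)):
        raise MapOverflowError(
            f"map step overflowed from (p={p!r}, n={n!r}); simulate with log_space=True"
        )
    return State(p1, n1)


def step_resource_only(n: float, params: ParamSet) -> float:
    """Consumer-free resource map ``n -> n * (delta_n + R / (1 + n))``.

    Strictly increasing in ``n`` with fixed points 0 and the carrying
    capacity ``n* = R / (1 - delta_n) - 1`` (when self-replenishing).
    """
    if n < 0 or not math.isfinite(n):
        raise ParameterError(f"resource density must be finite and >= 0, got {n!r}")
    return n * (params.delta_n + params.R / (1.0 + n))


def _exp_sat(x: float) -> float:
    """exp() that saturates to inf instead of raising OverflowError."""
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf


def log_step(lp: float, ln: float, params: ParamSet) -> tuple[float, float]:
    """One pulse of the exact logarithmic transform of the map.

    Operates on ``(log p, log n)``; ``-inf`` encodes an exactly-zero
    coordinate, for which the update reduces to the exact one-dimensional
    sub-map on the corresponding axis.  The resource update sums its two
    recruitment channels with log-sum-exp so that it stays accurate when
    both are far below double-precision underflow.
    """
    en = _exp_sat(ln)
    ep = _exp_sat(lp)
    # n/(1+sigma n^2) computed as 1/(e^-ln + sigma e^ln): immune to overflow
    inv = _exp_sat(-ln) + params.sigma * en
    q = 1.0 / inv if inv > 0 else math.inf
    lp1 = lp + math.log(params.delta_p + params.gamma_p * q)

    sn2 = params.sigma * en * en
    if math.isfinite(sn2):
        ldenom = math.log1p(sn2)
    else:
        ldenom = math.log(params.sigma) + 2.0 * ln
    consumption = params.gamma_n * _exp_sat(lp - ldenom)
    chan_adult = math.log(params.delta_n) - consumption
    chan_recruit = math.log(params.R) - ep - (math.log1p(en) if math.isfinite(en) else ln)
    ln1 = ln + float(np.logaddexp(chan_adult, chan_recruit))
    return lp1, ln1


@dataclass(frozen=True)
class Trajectory:
    """A simulated orbit indexed by pulse number ``m = 0..M``.

    Backed by log-density arrays so that states hundreds of log-units
    below 1 remain exact; ``-inf`` entries encode exactly-zero densities
    (the axes are forward-invariant).  ``p``/``n`` expose linear-space
    views, which may underflow to 0.0 for display purposes only.
    """

    params: ParamSet
    log_p: np.ndarray
    log_n: np.ndarray
    log_backed: bool = True

    def __post_init__(self) -> None:
        if len(self.log_p) != len(self.log_n):
            raise ValueError("log_p and log_n must have equal length")
        self.log_p.setflags(write=False)
        self.log_n.setflags(write=False)

    @property
    def p(self) -> np.ndarray:
        return np.exp(self.log_p)

    @property
    def n(self) -> np.ndarray:
        return np.exp(self.log_n)

    def __len__(self) -> int:
        return len(self.log_p)

    def __getitem__(self, m: int) -> State:
        return State(float(np.exp(self.log_p[m])), float(np.exp(self.log_n[m])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"m": np.arange(len(self)), "p": self.p, "n": self.n})

    def to_csv(self, path) -> None:
        """Write ``m,p,n`` rows with repr-roundtrip float formatting."""
        with open(path, "w", newline="\n") as fh:
            fh.write("m,p,n\n")
            p, n = self.p, self.n
            for m in range(len(self)):
                fh.write(f"{m},{float(p[m])!r},{float(n[m])!r}\n")


def simulate(s0: State | tuple[float, float], params: ParamSet, horizon: int,
             log_space: bool = True) -> Trajectory:
    """Iterate the map for ``horizon`` pulses from initial state ``s0``.

    With ``log_space=True`` (default) the exact logarithmic transform is
    iterated, which is stable arbitrarily close to the axes; zero
    coordinates are carried exactly as ``-inf`` on the corresponding 1-D
    sub-map.  Linear-space iteration is provided for cross-validation and
    raises :class:`MapOverflowError` if it leaves floating range.
    """
    if not isinstance(s0, State):
        s0 = State(*s0)
    horizon = int(horizon)
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")

    lps = np.empty(horizon + 1)
    lns = np.empty(horizon + 1)
    if log_space:
        lp = math.log(s0.p) if s0.p > 0 else -math.inf
        ln = math.log(s0.n) if s0.n > 0 else -math.inf
        lps[0], lns[0] = lp, ln
        for m in range(1, horizon + 1):
            lp, ln = log_step(lp, ln, params)
            lps[m], lns[m] = lp, ln
    else:
        s = s0
        with np.errstate(divide="ignore"):
            lps[0] = np.log(s.p)
            lns[0] = np.log(s.n)
            for m in range(1, horizon + 1):
                s = step(s, params)
                lps[m] = np.log(s.p)
                lns[m] = np.log(s.n)
    return Trajectory(params=params, log_p=lps, log_n=lns, log_backed=log_space)


@dataclass(frozen=True)
class Finding:
    name: str
    level: str  # "error" | "warn"
    passed: bool
    message: str


@dataclass(frozen=True)
class ValidationReport:
    findings: tuple[Finding, ...]

    @property
    def ok(self) -> bool:
        """True when no error-level finding failed (warnings allowed)."""
        return all(f.passed for f in self.findings if f.level == "error")

    @property
    def warnings(self) -> tuple[Finding, ...]:
        return tuple(f for f in self.findings if f.level == "warn" and not f.passed)

    def __str__(self) -> str:
        lines = []
        for f in self.findings:
            tag = "PASS" if f.passed else ("WARN" if f.level == "warn" else "FAIL")
            lines.append(f"[{tag}] {f.name}: {f.message}")
        return "\n".join(lines)


def validate_params(params: ParamSet) -> ValidationReport:
    """Report the model's parameter conditions as pass/fail/warn findings.

    Self-replenishment (``R > 1 - delta_n``) is error-level: without it
    the resource cannot persist and no carrying capacity exists.
    Group-defense relevance (``n* > 1/sqrt(sigma)``) is warning-level:
    the map is well defined without it, but defense then never protects
    resource densities below carrying capacity.
    """
    findings: list[Finding] = []
    findings.append(Finding(
        "positivity_and_ranges", "error", True,
        "survivals inside (0,1), rates positive (enforced at construction)",
    ))
    floor = 1.0 - params.delta_n
    ok_replenish = params.R > floor
    findings.append(Finding(
        "self_replenishment", "error", ok_replenish,
        f"R = {params.R!r} {'>' if ok_replenish else '<='} 1 - delta_n = {floor!r}",
    ))
    if ok_replenish and params.sigma > 0:
        n_star = params.R / floor - 1.0
        peak = 1.0 / math.sqrt(params.sigma)
        ok_defense = n_star > peak
        msg = f"carrying capacity n* = {n_star!r} {'>' if ok_defense else '<='} 1/sqrt(sigma) = {peak!r}"
    else:
        ok_defense = False
        msg = ("not evaluable: " +
               ("no positive carrying capacity" if not ok_replenish else "sigma = 0 (no group defense)"))
    findings.append(Finding("group_defense_relevance", "warn", ok_defense, msg))
    return ValidationReport(tuple(findings))
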