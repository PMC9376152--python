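"""Fixed points, stability and the transcritical bifurcation of the pulse map.

The map has up to four biologically relevant (first-quadrant) fixed points:

* extinction ``(0, 0)`` -- unstable whenever the resource is
  self-replenishing (the resource eigenvalue is ``delta_n + R > 1``);
* the consumer-free carrying capacity ``(0, n*)`` with
  ``n* = R / (1 - delta_n) - 1``;
* up to two coexistence saddles whose resource coordinates solve the
  consumer self-replacement condition
  ``(1 - delta_p) * (1 + sigma n**2) = gamma_p * n`` (a quadratic in ``n``
  created by the unimodal group-defense response) and whose consumer
  coordinates balance the resource recruitment equation.

The carrying-capacity state exchanges stability with the upper coexistence
branch in a transcritical bifurcation at
``gamma_p* = (1 - delta_p) * (1 + sigma n*^2) / n*``; the consumer-direction
eigenvalue there is ``lambda_1 = delta_p + gamma_p * n* / (1 + sigma n*^2)``,
which equals 1 exactly at the bifurcation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .model import ParamSet, ParameterError, State, step

__all__ = [
    "Equilibrium",
    "EquilibriumCatalog",
    "carrying_capacity",
    "bifurcation_value",
    "lambda1",
    "coexistence_pair",
    "jacobian",
    "catalog",
    "LABEL_EXTINCTION",
    "LABEL_CARRYING_CAPACITY",
    "LABEL_COEXISTENCE_LOW",
    "LABEL_COEXISTENCE_HIGH",
]

LABEL_EXTINCTION = "extinction"
LABEL_CARRYING_CAPACITY = "carrying_capacity"
LABEL_COEXISTENCE_LOW = "coexistence_low"
LABEL_COEXISTENCE_HIGH = "coexistence_high"

#: |modulus - 1| below this is treated as nonhyperbolic
NONHYPERBOLIC_TOL = 1e-9


@dataclass(frozen=True)
class Equilibrium:
    location: State
    label: str
    eigenvalues: tuple[complex, complex]
    stability: str  # stable | saddle | unstable | nonhyperbolic
    in_first_quadrant: bool

    def residual(self, params: ParamSet) -> float:
        """Max-coordinate residual of the fixed-point equations under the map."""
        nxt = step(self.location, params)
        return max(abs(nxt.p - self.location.p), abs(nxt.n - self.location.n))


@dataclass(frozen=True)
class EquilibriumCatalog:
    params: ParamSet
    equilibria: tuple[Equilibrium, ...]
    gamma_p_star: float
    lambda_1: float

    def get(self, label: str) -> Optional[Equilibrium]:
        for eq in self.equilibria:
            if eq.label == label:
                return eq
        return None

    @property
    def has_stable(self) -> bool:
        return any(eq.stability == "stable" for eq in self.equilibria)


def carrying_capacity(params: ParamSet) -> float:
    """Positive fixed point ``n* = R / (1 - delta_n) - 1`` of the consumer-free map."""
    if not params.self_replenishing:
        raise ParameterError(
            f"no positive carrying capacity: R = {params.R!r} <= 1 - delta_n = {1 - params.delta_n!r}"
        )
    return params.R / (1.0 - params.delta_n) - 1.0


def bifurcation_value(params: ParamSet) -> float:
    """Transcritical bifurcation point ``gamma_p* = (1-delta_p)(1+sigma n*^2)/n*``.

    At ``gamma_p = gamma_p*`` the consumer eigenvalue at the carrying
    capacity equals 1 exactly and the upper coexistence branch collides
    with ``(0, n*)``.
    """
    n_star = carrying_capacity(params)
    return (1.0 - params.delta_p) * (1.0 + params.sigma * n_star ** 2) / n_star


def lambda1(params: ParamSet) -> float:
    """Consumer-direction eigenvalue at ``(0, n*)``:
    ``lambda_1 = delta_p + gamma_p n* / (1 + sigma n*^2)``.

    Governs the invasion of a rare consumer at resource carrying capacity;
    ``lambda_1 > 1`` iff ``gamma_p > gamma_p*``.
    """
    n_star = carrying_capacity(params)
    return params.delta_p + params.gamma_p * n_star / (1.0 + params.sigma * n_star ** 2)


def coexistence_n_roots(params: ParamSet) -> list[float]:
    """Resource coordinates of candidate coexistence states (ascending).

    Roots of ``sigma (1-delta_p) n^2 - gamma_p n + (1-delta_p) = 0``.
    With ``sigma = 0`` the group-defense hump disappears, the quadratic
    degenerates (the upper branch escapes to infinity) and no saddle pair
    exists; an empty list is returned.
    """
    if params.sigma == 0:
        return []
    one_m = 1.0 - params.delta_p
    disc = params.gamma_p ** 2 - 4.0 * params.sigma * one_m ** 2
    if disc < 0:
        return []
    root = math.sqrt(disc)
    den = 2.0 * params.sigma * one_m
    return [(params.gamma_p - root) / den, (params.gamma_p + root) / den]


def _recruitment_balance(n: float, params: ParamSet):
    """Function of p whose root is the consumer density balancing resource recruitment."""
    a = 1.0 + params.sigma * n * n

    def f(p: float) -> float:
        return (params.delta_n * math.exp(-params.gamma_n * p / a)
                + params.R * math.exp(-p) / (1.0 + n) - 1.0)

    return f


def coexistence_pair(params: ParamSet, p_max_cap: float = 1e6) -> list[State]:
    """First-quadrant coexistence fixed points, ordered by resource density.

    For each positive root ``n`` of the consumer self-replacement
    quadratic, the consumer coordinate solves
    ``1 = delta_n exp(-gamma_n p / (1+sigma n^2)) + R exp(-p) / (1+n)``,
    which is strictly decreasing in ``p``; a positive solution exists iff
    ``n < n*``.  Root-finding is bracketed (bracket grown geometrically
    from 1) and resolved to ~1e-12.

    Returns 0, 1 or 2 states: both branches for ``gamma_p`` below the
    bifurcation (when the discriminant is positive), only the lower branch
    above it (the upper branch leaves the first quadrant), none when the
    discriminant is negative or ``sigma = 0``.
    """
    out: list[State] = []
    for n in coexistence_n_roots(params):
        if n <= 0:
            continue
        f = _recruitment_balance(n, params)
        if f(0.0) <= 0.0:
            continue  # balance already below replacement at p = 0: no positive root
        hi = 1.0
        while f(hi) > 0.0:
            hi *= 2.0
            if hi > p_max_cap:
                raise RuntimeError(
                    f"no sign change of recruitment balance on (0, {p_max_cap!r}] at n = {n!r}"
                )
        p = brentq(f, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
        out.append(State(float(p), float(n)))
    return out


def jacobian(s: State, params: ParamSet) -> np.ndarray:
    """Analytic Jacobian of the map at state ``s``.

    Entries follow from differentiating the pulse map; at ``(0, n*)`` the
    matrix is triangular with eigenvalues ``lambda_1`` and
    ``delta_n + R/(1+n*)^2``, and at the origin ``delta_p`` and
    ``delta_n + R``.
    """
    if not isinstance(s, State):
        s = State(*s)
    p, n = s.p, s.n
    sig, gp, gn, dn, R = params.sigma, params.gamma_p, params.gamma_n, params.delta_n, params.R
    den = 1.0 + sig * n * n
    f = n / den                      # functional response
    fprime = (1.0 - sig * n * n) / den ** 2
    e_cons = math.exp(-gn * p / den)
    e_p = math.exp(-p)
    dpdp = params.delta_p + gp * f
    dpdn = gp * p * fprime
    adult = dn * n * e_cons
    recruit = R * n * e_p / (1.0 + n)
    dndp = -adult * gn / den - recruit
    dndn = (dn * e_cons
            + adult * (2.0 * sig * gn * p * n) / den ** 2
            + R * e_p / (1.0 + n) ** 2)
    return np.array([[dpdp, dpdn], [dndp, dndn]])


def _classify(eigvals: np.ndarray, tol: float = NONHYPERBOLIC_TOL) -> str:
    mods = np.abs(eigvals)
    if np.any(np.abs(mods - 1.0) < tol):
        return "nonhyperbolic"
    if np.all(mods < 1.0):
        return "stable"
    if np.all(mods > 1.0):
        return "unstable"
    return "saddle"


def _make_equilibrium(loc: State, label: str, params: ParamSet) -> Equilibrium:
    eig = np.linalg.eigvals(jacobian(loc, params))
    return Equilibrium(
        location=loc,
        label=label,
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        stability=_classify(eig),
        in_first_quadrant=loc.p >= 0 and loc.n >= 0,
    )


def catalog(params: ParamSet) -> EquilibriumCatalog:
    """All first-quadrant fixed points with eigenvalues and stability labels.

    Requires a self-replenishing resource (so the carrying capacity
    exists).  Coexistence entries are labelled ``coexistence_low`` /
    ``coexistence_high`` by their resource coordinate.
    """
    n_star = carrying_capacity(params)
    entries = [
        _make_equilibrium(State(0.0, 0.0), LABEL_EXTINCTION, params),
        _make_equilibrium(State(0.0, n_star), LABEL_CARRYING_CAPACITY, params),
    ]
    pair = coexistence_pair(params)
    if len(pair) == 1:
        entries.append(_make_equilibrium(pair[0], LABEL_COEXISTENCE_LOW, params))
    elif len(pair) == 2:
        entries.append(_make_equilibrium(pair[0], LABEL_COEXISTENCE_LOW, params))
        entries.append(_make_equilibrium(pair[1], LABEL_COEXISTENCE_HIGH, params))
    return EquilibriumCatalog(
        params=params,
        equilibria=tuple(entries),
        gamma_p_star=bifurcation_value(params),
        lambda_1=lambda1(params),
    )
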