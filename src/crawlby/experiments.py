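"""One-command reproduction of the study's figure-level experiments.

Each experiment (``fig1`` ... ``fig6``) bundles a parameter set, an initial
state, a horizon and (for the sweeps) a grid, all defaulting to the values
used in the corresponding published figure:

* ``fig1`` -- time series below the bifurcation (``gamma_p = 1``): the
  resource crashes under a high initial consumer load, crawls by
  extinction, then recovers to carrying capacity while the consumer dies
  out.
* ``fig2`` -- observed vs estimated resource recovery time as the initial
  consumer density ``p0`` is swept.
* ``fig3`` -- consumer-resource cycles above the bifurcation
  (``gamma_p = 3``; override ``gamma_p = 8`` for the long-period variant).
* ``fig4`` -- observed vs estimated consumer escape-from-rarity time as
  ``p0 = eps`` is swept just below carrying capacity.
* ``fig5`` -- ghost regime time series at ``gamma_p = 0.9912 gamma_p*``.
* ``fig6`` -- ghost escape time across bifurcation offsets with the
  power-law fit.

The model is fully deterministic, so outputs are byte-identical across
runs.  All numeric CSV fields use repr-roundtrip formatting.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from . import equilibria, transients
from .model import ParamSet, ParameterError, State, simulate

__all__ = [
    "SweepSpec",
    "ExperimentSpec",
    "EXPERIMENT_NAMES",
    "BASELINE",
    "build_experiment",
    "load_config",
    "run_experiment",
    "collapse_recovery_cycles",
]

#: shared parameter values of all published figures (gamma_p varies per figure)
BASELINE = ParamSet(delta_p=0.9, delta_n=0.8, gamma_p=1.0, gamma_n=1.0, sigma=2.67, R=2.0)

EXPERIMENT_NAMES = ("fig1", "fig2", "fig3", "fig4", "fig5", "fig6")

_CONFIG_KEYS = ("name", "delta_p", "delta_n", "gamma_p", "gamma_n", "sigma", "R",
                "p0", "n0", "horizon", "log_space")

_SWEEP_VARIABLES = ("p0", "epsilon", "gamma_p")


@dataclass(frozen=True)
class SweepSpec:
    variable: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.variable not in _SWEEP_VARIABLES:
            raise ParameterError(
                f"sweep variable must be one of {_SWEEP_VARIABLES}, got {self.variable!r}"
            )


@dataclass(frozen=True)
class ExperimentSpec:
    name: str
    params: ParamSet
    initial: State
    horizon: int
    sweep: Optional[SweepSpec] = None
    log_space: bool = True

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_NAMES:
            raise ParameterError(
                f"unknown experiment {self.name!r}; known: {', '.join(EXPERIMENT_NAMES)}"
            )
        if self.horizon < 1:
            raise ParameterError(f"horizon must be >= 1, got {self.horizon}")


def _fig5_gamma_p(params: ParamSet) -> float:
    return 0.9912 * equilibria.bifurcation_value(params)


def build_experiment(name: str, **overrides) -> ExperimentSpec:
    """Build a figure experiment from built-in defaults plus overrides.

    Overrides accept the flat config keys (model parameters, ``p0``,
    ``n0``, ``horizon``, ``log_space``).  ``fig5``'s default ``gamma_p``
    is ``0.9912 * gamma_p*`` computed from the (possibly overridden)
    remaining parameters; an explicit ``gamma_p`` override wins.
    """
    if name not in EXPERIMENT_NAMES:
        raise ParameterError(f"unknown experiment {name!r}; known: {', '.join(EXPERIMENT_NAMES)}")
    unknown = set(overrides) - set(_CONFIG_KEYS)
    if unknown:
        raise ParameterError(
            f"unknown keys {sorted(unknown)}; valid keys: {', '.join(_CONFIG_KEYS)}"
        )

    gamma_p_default = {"fig1": 1.0, "fig2": 1.0, "fig3": 3.0, "fig4": 3.0,
                       "fig5": None, "fig6": None}[name]
    param_fields = {f.name: getattr(BASELINE, f.name) for f in dataclasses.fields(ParamSet)}
    if gamma_p_default is not None:
        param_fields["gamma_p"] = gamma_p_default
    explicit_gamma_p = "gamma_p" in overrides
    for key in param_fields:
        if key in overrides:
            param_fields[key] = float(overrides[key])
    if name == "fig5" and not explicit_gamma_p:
        param_fields["gamma_p"] = _fig5_gamma_p(ParamSet(**param_fields))
    if name == "fig6" and not explicit_gamma_p:
        # placeholder; the sweep sets gamma_p = gamma_p* - eps per point
        param_fields["gamma_p"] = BASELINE.gamma_p
    params = ParamSet(**param_fields)

    horizon = int(overrides.get("horizon", {"fig1": 200, "fig2": 2000, "fig3": 5000,
                                            "fig4": 5000, "fig5": 10000, "fig6": 50000}[name]))
    p0 = float(overrides.get("p0", 10.0))
    n0 = float(overrides.get("n0", 1.0))
    log_space = bool(overrides.get("log_space", True))

    sweep = None
    if name == "fig2":
        sweep = SweepSpec("p0", tuple(np.geomspace(10.0, 1e6, 20)))
    elif name == "fig4":
        sweep = SweepSpec("epsilon", tuple(np.geomspace(1e-8, 1e-2, 20)))
    elif name == "fig6":
        sweep = SweepSpec("epsilon", tuple(transients.default_epsilon_grid(params)))
    return ExperimentSpec(name=name, params=params, initial=State(p0, n0),
                          horizon=horizon, sweep=sweep, log_space=log_space)


def _parse_value(key: str, raw: str):
    if key == "name":
        return raw
    if key == "log_space":
        low = raw.lower()
        if low in ("true", "1", "yes", "on"):
            return True
        if low in ("false", "0", "no", "off"):
            return False
        raise ParameterError(f"cannot parse log_space value {raw!r} as a boolean")
    if key == "horizon":
        return int(raw)
    return float(raw)


def load_config(path) -> ExperimentSpec:
    """Parse a flat ``key = value`` config file into an experiment spec.

    Lines are ``key = value`` with ``#`` comments; the only required key
    is ``name`` (one of ``fig1`` ... ``fig6``); remaining keys override
    that figure's built-in defaults.  Unknown keys raise with the list of
    valid keys.
    """
    text = Path(path).read_text()
    overrides: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        if "=" not in body:
            raise ParameterError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, raw = (part.strip() for part in body.split("=", 1))
        if key not in _CONFIG_KEYS:
            raise ParameterError(
                f"{path}:{lineno}: unknown key {key!r}; valid keys: {', '.join(_CONFIG_KEYS)}"
            )
        try:
            overrides[key] = _parse_value(key, raw)
        except ValueError as exc:
            raise ParameterError(f"{path}:{lineno}: cannot parse {key} value {raw!r}: {exc}") from exc
    if "name" not in overrides:
        raise ParameterError(f"{path}: config must set 'name' (one of {', '.join(EXPERIMENT_NAMES)})")
    name = overrides.pop("name")
    return build_experiment(name, **overrides)


def _write_csv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(
                str(v) if isinstance(v, (int, np.integer)) or v is None else repr(float(v))
                for v in row
            ) + "\n")


def collapse_recovery_cycles(traj, n_star: float,
                             low_frac: float = 1e-3, high_frac: float = 0.5) -> int:
    """Count completed resource collapse-recovery cycles on a trajectory.

    A cycle completes when the resource, having fallen below
    ``low_frac * n*``, climbs back above ``high_frac * n*``.
    """
    low_thr = math.log(low_frac * n_star)
    high_thr = math.log(high_frac * n_star)
    collapsed, cycles = False, 0
    for v in traj.log_n:
        if not collapsed and v < low_thr:
            collapsed = True
        elif collapsed and v > high_thr:
            collapsed = False
            cycles += 1
    return cycles


def _params_dict(params: ParamSet) -> dict:
    return {f.name: getattr(params, f.name) for f in dataclasses.fields(ParamSet)}


def run_experiment(spec: ExperimentSpec, out_dir=".", plot: bool = False) -> dict:
    """Run one figure experiment; write its CSV/JSON outputs; return the summary.

    The summary always reports ``gamma_p_star``, ``lambda_1``, ``n_star``,
    ``coexistence`` (list of ``[p, n]``), ``escape_time`` (ghost escape,
    or null) and ``fit`` (power-law ``{A, B, r_squared}``, or null),
    plus per-experiment extras.  The summary is also written as
    ``<name>_summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = spec.params
    cat = equilibria.catalog(params)
    summary: dict = {
        "name": spec.name,
        "params": _params_dict(params),
        "horizon": spec.horizon,
        "gamma_p_star": cat.gamma_p_star,
        "lambda_1": cat.lambda_1,
        "n_star": equilibria.carrying_capacity(params),
        "coexistence": [[eq.location.p, eq.location.n]
                        for eq in cat.equilibria
                        if eq.label.startswith("coexistence")],
        "escape_time": None,
        "fit": None,
    }
    outputs: list[Path] = []

    if spec.name in ("fig1", "fig3", "fig5"):
        traj = simulate(spec.initial, params, spec.horizon, log_space=spec.log_space)
        traj_path = out / f"{spec.name}_trajectory.csv"
        traj.to_csv(traj_path)
        outputs.append(traj_path)
        final = traj[len(traj) - 1]
        summary["final_state"] = [final.p, final.n]
        summary["has_stable_fixed_point"] = cat.has_stable
        summary["collapse_recovery_cycles"] = collapse_recovery_cycles(traj, summary["n_star"])
        if spec.name == "fig5":
            summary["escape_time"] = transients.ghost_escape_time(traj, cat)
        if plot:
            _plot_timeseries(traj, out / f"{spec.name}_timeseries.png")

    elif spec.name == "fig2":
        rows = []
        for p0 in spec.sweep.values:
            traj = simulate(State(p0, spec.initial.n), params, spec.horizon,
                            log_space=spec.log_space)
            obs = transients.recovery_time_observed(traj)
            est = transients.recovery_time_estimate(params, p0)
            rows.append((p0, obs, est))
        sweep_path = out / "fig2_recovery_sweep.csv"
        _write_csv(sweep_path, ("p0", "observed", "estimated"), rows)
        outputs.append(sweep_path)
        slope, intercept = transients.scaling_slope(
            [(math.log(1.0 / p0), obs) for p0, obs, _ in rows if obs is not None])
        summary["scaling_slope"] = slope
        summary["scaling_slope_predicted"] = 1.0 / (-math.log(params.delta_p))
        if plot:
            _plot_sweep(rows, "p0", "recovery time", out / "fig2_sweep.png")

    elif spec.name == "fig4":
        n_star = summary["n_star"]
        rows = []
        for eps in spec.sweep.values:
            traj = simulate(State(eps, n_star - eps), params, spec.horizon,
                            log_space=spec.log_space)
            obs = transients.escape_time_observed(traj)
            est = transients.escape_time_estimate(params, eps)
            rows.append((eps, obs, est))
        sweep_path = out / "fig4_escape_sweep.csv"
        _write_csv(sweep_path, ("epsilon", "observed", "estimated"), rows)
        outputs.append(sweep_path)
        slope, intercept = transients.scaling_slope(
            [(math.log(eps), obs) for eps, obs, _ in rows if obs is not None])
        summary["scaling_slope"] = slope
        summary["scaling_slope_predicted"] = 1.0 / math.log(cat.lambda_1)
        if plot:
            _plot_sweep(rows, "epsilon", "escape time", out / "fig4_sweep.png")

    elif spec.name == "fig6":
        sample = transients.tau_sweep(params, spec.sweep.values, spec.initial, spec.horizon)
        gps = equilibria.bifurcation_value(params)
        rows = [(eps, gps - eps, tau) for eps, tau in sample]
        sweep_path = out / "fig6_tau_sweep.csv"
        _write_csv(sweep_path, ("epsilon", "gamma_p", "tau"), rows)
        outputs.append(sweep_path)
        fit = transients.fit_power_law(sample, gamma_p_star=gps)
        summary["fit"] = {"A": fit.A, "B": fit.B, "r_squared": fit.r_squared}
        fit_path = out / "fig6_powerlaw.json"
        fit_path.write_text(json.dumps(summary["fit"], indent=2) + "\n")
        outputs.append(fit_path)
        if plot:
            _plot_sweep([(e, t, fit.predict(e)) for e, _, t in rows],
                        "epsilon", "tau", out / "fig6_sweep.png")

    summary_path = out / f"{spec.name}_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    outputs.append(summary_path)
    summary["outputs"] = [str(p) for p in outputs]
    return summary


def _plot_timeseries(traj, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    m = np.arange(len(traj))
    axes[0].semilogy(m, traj.p, lw=0.8)
    axes[0].set_ylabel("consumer p")
    axes[1].semilogy(m, traj.n, lw=0.8)
    axes[1].set_ylabel("resource n")
    axes[1].set_xlabel("pulse m")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_sweep(rows, xlabel: str, ylabel: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [r[0] for r in rows]
    obs = [r[1] for r in rows]
    est = [r[2] for r in rows]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(xs, obs, "o", label="observed")
    ax.plot(xs, est, "-", label="estimated")
    ax.set_xscale("log")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
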