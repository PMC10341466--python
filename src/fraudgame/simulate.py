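"""Deterministic simulation of the replicator dynamics.

Houses the three scenario presets of the originating numerical study,
adaptive Runge-Kutta integration of the vector field, convergence and
crossing-time diagnostics, single-parameter sweeps, and a seeded sampler
of random valid parameter sets for property testing.

The presets share the initial state (0.8, 0.5, 0.2) and differ only in
parameters; under the published dynamics they converge to full
disengagement (0,0,0), supervised fraud (0,0,1) and deterred fraud
(1,0,1) respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .game_model import MixedState, ParameterSet, validate_parameters
from .replicator import DEFAULT_MODE, DynamicsMode, _coerce_mode, rates, vector_field
from .stability import ConditionFlags, StabilityReport, condition_flags, stability_report

__all__ = [
    "SCENARIO_PRESETS",
    "DEFAULT_INITIAL_STATE",
    "ScenarioConfig",
    "Trajectory",
    "ScenarioResult",
    "MetricSpec",
    "SweepRow",
    "SweepResult",
    "scenario_parameters",
    "scenario_config",
    "integrate",
    "converged_state",
    "time_to_threshold",
    "run_scenario",
    "parameter_sweep",
    "parse_metric",
    "sample_valid_parameters",
]

#: Scenario parameter presets (all currency values as printed in the
#: originating study's three simulation scenarios).
SCENARIO_PRESETS: dict[int, ParameterSet] = {
    1: ParameterSet(Ch1=8, Ch2=5, Ct1=2, Ct2=1, Cg=9, Ih1=9, Ih2=10, It1=3,
                    It2=4, Ig1=8, Ig2=5, Ah=2, Ph=2, Pt=1, Ag=2, Pg=3),
    2: ParameterSet(Ch1=7, Ch2=5, Ct1=2, Ct2=1, Cg=5.5, Ih1=8, Ih2=9, It1=2.5,
                    It2=3, Ig1=8, Ig2=5, Ah=2, Ph=0.8, Pt=0.5, Ag=2, Pg=5),
    3: ParameterSet(Ch1=6, Ch2=4.5, Ct1=2, Ct2=1, Cg=5, Ih1=6.5, Ih2=7, It1=2.5,
                    It2=3, Ig1=5.5, Ig2=4, Ah=0.6, Ph=4.5, Pt=1.2, Ag=4.9, Pg=3),
}

#: Shared initial mixed state of all three scenario presets.
DEFAULT_INITIAL_STATE = MixedState(0.8, 0.5, 0.2)

#: Default integration horizon.  The study plots 10-20 time units; a
#: longer horizon makes endpoint assertions robust without changing them.
DEFAULT_T_END = 50.0


def scenario_parameters(preset_id: int) -> ParameterSet:
    """The parameter set of scenario preset 1, 2 or 3."""
    try:
        return SCENARIO_PRESETS[preset_id]
    except KeyError:
        raise ValueError(f"unknown scenario preset {preset_id!r}; choose 1, 2 or 3") from None


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to integrate one trajectory."""

    params: ParameterSet
    initial_state: MixedState = DEFAULT_INITIAL_STATE
    t_end: float = DEFAULT_T_END
    mode: DynamicsMode = DEFAULT_MODE
    preset_id: int | None = None
    n_points: int = 201
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.t_end < 0:
            raise ValueError("t_end must be non-negative")
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")
        if not self.initial_state.in_unit_cube:
            raise ValueError("initial state must lie in [0,1]^3")
        object.__setattr__(self, "mode", _coerce_mode(self.mode))


def scenario_config(preset_id: int, overrides: Mapping[str, float] | None = None,
                    t_end: float = DEFAULT_T_END,
                    mode: DynamicsMode = DEFAULT_MODE) -> ScenarioConfig:
    """Build a config from a preset, optionally overriding parameters.

    The overridden set must still pass core validation.
    """
    params = scenario_parameters(preset_id)
    if overrides:
        params = params.replace(**dict(overrides))
        violations = validate_parameters(params)
        if violations:
            raise ValueError(f"overridden parameters invalid: {', '.join(violations)}")
    return ScenarioConfig(params=params, t_end=t_end, mode=mode, preset_id=preset_id)


@dataclass(frozen=True)
class Trajectory:
    """A time-indexed solution of the replicator ODE.

    ``states`` has one row per time, clamped into [0,1] (the cube is
    forward-invariant in exact arithmetic; clamping removes integrator
    float drift).
    """

    times: np.ndarray
    states: np.ndarray
    config: ScenarioConfig

    @property
    def final_state(self) -> MixedState:
        return MixedState(*self.states[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.times,
            "x": self.states[:, 0],
            "y": self.states[:, 1],
            "z": self.states[:, 2],
        })


def integrate(config: ScenarioConfig) -> Trajectory:
    """Integrate the replicator field with adaptive RK45.

    Dense output is sampled at ``n_points`` evenly spaced times and
    clamped into the unit cube.  An integration failure raises with the
    last valid state in the message.
    """
    y0 = np.array(config.initial_state.as_tuple())
    t_eval = np.linspace(0.0, config.t_end, config.n_points)
    if config.t_end == 0.0:
        states = np.repeat(y0[None, :], 2, axis=0)
        return Trajectory(np.array([0.0, 0.0]), states, config)
    # Evaluate the field at the state clamped into the cube: a no-op on
    # the exact solution (the cube is invariant) but it stops adaptive
    # overshoot past a face from feeding the anti-restoring polynomial
    # continuation outside [0,1].
    sol = solve_ivp(
        lambda _t, s: rates(config.params, np.clip(s, 0.0, 1.0), config.mode),
        (0.0, config.t_end), y0, method="RK45",
        t_eval=t_eval, rtol=config.rtol, atol=config.atol,
    )
    if not sol.success:
        last = sol.y[:, -1] if sol.y.size else y0
        raise RuntimeError(
            f"integration failed: {sol.message} (last valid state {tuple(last)})"
        )
    states = np.clip(sol.y.T, 0.0, 1.0)
    return Trajectory(sol.t, states, config)


def converged_state(traj: Trajectory, tol: float = 1e-3) -> MixedState | None:
    """Final state if the trajectory has settled, else ``None``.

    Settled means that over the last 10% of the time span both the rate
    norm stays below ``2*tol`` and the state moves less than ``tol``
    (infinity norm against the final state).
    """
    t_window = traj.times[-1] - 0.1 * (traj.times[-1] - traj.times[0])
    window = traj.states[traj.times >= t_window]
    if len(window) < 2:
        window = traj.states[-2:]
    final = traj.states[-1]
    if np.max(np.abs(window - final)) >= tol:
        return None
    for state in window:
        rate = rates(traj.config.params, state, traj.config.mode)
        if np.max(np.abs(rate)) >= 2.0 * tol:
            return None
    return traj.final_state


def time_to_threshold(traj: Trajectory, component: Literal["x", "y", "z"],
                      level: float, direction: Literal["below", "above"]) -> float | None:
    """First time the component crosses ``level``, by linear interpolation.

    ``None`` when the level is never reached (including trajectories that
    start past it moving the wrong way — crossing means attaining the
    target side having started off it, or starting there already).
    """
    if component not in ("x", "y", "z"):
        raise ValueError(f"component must be x, y or z, got {component!r}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    values = traj.states[:, "xyz".index(component)]
    on_side = values < level if direction == "below" else values > level
    if on_side[0]:
        return float(traj.times[0])
    idx = np.flatnonzero(on_side)
    if idx.size == 0:
        return None
    i = int(idx[0])
    t0, t1 = traj.times[i - 1], traj.times[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) * (t1 - t0) / (v1 - v0))


@dataclass(frozen=True)
class ScenarioResult:
    """Trajectory plus the stability context of its parameter set."""

    trajectory: Trajectory
    report: StabilityReport
    flags: ConditionFlags
    converged: MixedState | None


def run_scenario(preset_id: int, overrides: Mapping[str, float] | None = None,
                 t_end: float = DEFAULT_T_END,
                 mode: DynamicsMode = DEFAULT_MODE) -> ScenarioResult:
    """Integrate a scenario preset and attach corner classifications."""
    config = scenario_config(preset_id, overrides, t_end, mode)
    traj = integrate(config)
    report = stability_report(config.params, config.mode)
    return ScenarioResult(
        trajectory=traj,
        report=report,
        flags=report.flags,
        converged=converged_state(traj),
    )


@dataclass(frozen=True)
class MetricSpec:
    """What to record per sweep value.

    ``kind='final'`` records the final state only; ``kind='time_to'``
    additionally records the first crossing time of ``component`` past
    ``level`` in ``direction``.
    """

    kind: Literal["final", "time_to"] = "final"
    component: Literal["x", "y", "z"] | None = None
    level: float | None = None
    direction: Literal["below", "above"] | None = None


def parse_metric(spec: str) -> MetricSpec:
    """Parse a metric string: ``final`` or ``time-to:z<0.1`` / ``time-to:x>0.9``."""
    spec = spec.strip()
    if spec == "final":
        return MetricSpec(kind="final")
    if spec.startswith("time-to:"):
        body = spec[len("time-to:"):]
        for op, direction in (("<", "below"), (">", "above")):
            if op in body:
                component, level = body.split(op, 1)
                component = component.strip()
                if component not in ("x", "y", "z"):
                    raise ValueError(f"unknown component {component!r} in metric {spec!r}")
                return MetricSpec("time_to", component, float(level), direction)
    raise ValueError(f"cannot parse metric {spec!r}; expected 'final' or 'time-to:z<0.1'")


@dataclass(frozen=True)
class SweepRow:
    value: float
    valid: bool
    final_state: MixedState | None = None
    metric_value: float | None = None
    note: str | None = None


@dataclass(frozen=True)
class SweepResult:
    """One integration per swept value of a single parameter."""

    parameter: str
    metric: MetricSpec
    rows: tuple[SweepRow, ...]

    def metric_values(self) -> list[float | None]:
        return [row.metric_value for row in self.rows]

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            final = row.final_state.as_tuple() if row.final_state else (None,) * 3
            records.append({
                self.parameter: row.value, "valid": row.valid,
                "x_final": final[0], "y_final": final[1], "z_final": final[2],
                "metric": row.metric_value, "note": row.note,
            })
        return pd.DataFrame.from_records(records)


def parameter_sweep(base: ScenarioConfig, name: str, values: Sequence[float],
                    metric: MetricSpec | str = MetricSpec()) -> SweepResult:
    """Integrate ``base`` once per value of parameter ``name``.

    A value that breaks validation is recorded as an invalid row and the
    sweep continues; ordering of ``values`` is preserved.
    """
    if isinstance(metric, str):
        metric = parse_metric(metric)
    rows: list[SweepRow] = []
    for value in values:
        try:
            params = base.params.replace(**{name: value})
            violations = validate_parameters(params)
            if violations:
                raise ValueError(f"constraint violations: {', '.join(violations)}")
            traj = integrate(replace(base, params=params))
        except (ValueError, RuntimeError) as exc:
            rows.append(SweepRow(value=value, valid=False, note=str(exc)))
            continue
        metric_value = None
        note = None
        if metric.kind == "time_to":
            metric_value = time_to_threshold(traj, metric.component, metric.level,
                                             metric.direction)
            if metric_value is None:
                note = "not reached"
        rows.append(SweepRow(value=value, valid=True, final_state=traj.final_state,
                             metric_value=metric_value, note=note))
    return SweepResult(parameter=name, metric=metric, rows=tuple(rows))


# uniform sampling ranges for the rejection sampler
_COST_INCOME_HIGH = 10.0
_REWARD_FINE_HIGH = 5.0
_COST_INCOME_FIELDS = ("Ch1", "Ch2", "Ct1", "Ct2", "Cg",
                       "Ih1", "Ih2", "It1", "It2", "Ig1", "Ig2")
_REWARD_FINE_FIELDS = ("Ah", "Ph", "Pt", "Ag", "Pg")


def sample_valid_parameters(seed: int, condition: Literal["any", "A", "B", "C"] = "any",
                            max_draws: int = 100_000) -> ParameterSet:
    """Draw one strictly valid parameter set by seeded rejection sampling.

    Costs and incomes are uniform on (0, 10], rewards and fines on
    (0, 5]; draws are rejected until the ordering constraints (and, if
    requested, condition A, B or C) hold.  The same seed always returns
    the same set.
    """
    if condition not in ("any", "A", "B", "C"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    for _ in range(max_draws):
        draw = {name: _COST_INCOME_HIGH * (1.0 - rng.random())
                for name in _COST_INCOME_FIELDS}
        draw.update({name: _REWARD_FINE_HIGH * (1.0 - rng.random())
                     for name in _REWARD_FINE_FIELDS})
        params = ParameterSet(**draw)
        if validate_parameters(params, strict=True):
            continue
        if condition != "any" and not getattr(condition_flags(params), condition):
            continue
        return params
    raise RuntimeError(
        f"rejection sampling budget of {max_draws} draws exhausted "
        f"(condition {condition!r})"
    )
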