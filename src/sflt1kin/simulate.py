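"""Simulation protocols for constitutive-secretion and pulse-chase experiments.

Both protocols mirror how the corresponding cell-culture experiments are run:

* **Constitutive secretion** — cells are pre-cultured to an intracellular
  steady state (pre-simulation from an empty system until I changes by less
  than ``ss_rel_change`` over a sliding ``ss_window``), then the media change
  at t=0 resets extracellular sFLT1 to zero while leaving the intracellular
  pool and its delay history untouched, and secretion into fresh media is
  followed for 24-72 h.

* **Pulse-chase** — the system starts empty (no *labeled* protein exists
  before the pulse); labeled production runs at rate alpha for
  ``pulse_length`` (default 20 min), then at t=0 the media is changed
  (X reset to 0) and production of labeled protein stops (or decays as
  ``alpha * exp(-kappa t)`` in models with production decay) while the chase
  is followed for 10 h.

Discontinuities (the media-change reset, the production switch-off) are
handled by segmenting the integration at the known event times.  The delay
history is carried across segment boundaries as an interpolant of the
already-computed intracellular trajectory; before the very first segment the
history is identically zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _integrate
from .model_core import ModelSpec, ParameterSet, Phase, SystemState

__all__ = [
    "ScenarioConfig",
    "Trajectory",
    "History",
    "ConvergenceError",
    "IntegrationDivergedError",
    "integrate_segment",
    "run_to_steady_state",
    "simulate_constitutive",
    "simulate_pulse_chase",
    "normalize_trajectory",
]

#: Delays shorter than this (0.036 s) are dynamically indistinguishable from
#: no delay at the tolerances used and are integrated as plain ODEs.
TAU_MIN = 1e-5


class ConvergenceError(RuntimeError):
    """Pre-simulation failed to reach steady state within the cap."""


class IntegrationDivergedError(RuntimeError):
    """The trajectory blew up (genuinely unstable parameter combination)."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Timing and convergence settings shared by both protocols."""

    duration: float = 72.0  # h of reported simulation (24/72 constitutive, 10 chase)
    pulse_length: float = 1.0 / 3.0  # h (20 min labeling pulse)
    report_interval: float = 1.0 / 60.0  # h (1-min reporting grid)
    ss_rel_change: float = 0.005  # steady-state criterion on I
    ss_window: float = 20.0  # h window for the criterion
    presim_cap: float = 2000.0  # h; give up on steady state beyond this

    def __post_init__(self) -> None:
        for name in ("duration", "pulse_length", "report_interval", "ss_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.report_interval > self.duration:
            raise ValueError("report_interval must not exceed duration")


@dataclass(frozen=True)
class History:
    """Continuous interpolant of past intracellular sFLT1 (zero before data)."""

    times: np.ndarray
    I: np.ndarray

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        return np.interp(t, self.times, self.I, left=0.0)


@dataclass
class Trajectory:
    """Reported time series of both species with phase annotations.

    ``I_delayed`` carries I(t - tau) on the same grid (equal to ``I`` for
    non-delayed models), which makes flux reconstruction possible without
    re-integrating.
    """

    times: np.ndarray  # h, strictly increasing
    I: np.ndarray  # #/cell (or relative units after normalization)
    X: np.ndarray
    phase: np.ndarray  # per-point phase label
    I_delayed: np.ndarray
    scenario: str
    params: ParameterSet
    spec: ModelSpec
    units: str = "#/cell"

    def value_at(self, species: str, time: float | np.ndarray):
        series = {"I": self.I, "X": self.X}[species]
        return np.interp(time, self.times, series)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for species, series in (("I", self.I), ("X", self.X)):
            frames.append(
                pd.DataFrame(
                    {
                        "time_h": self.times,
                        "species": species,
                        "value": series,
                        "phase": self.phase,
                        "units": self.units,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# internals


def _effective_tau(params: ParameterSet, spec: ModelSpec) -> float:
    if spec.has_delay and params.tau > TAU_MIN:
        return params.tau
    return 0.0


def _choose_step(
    params: ParameterSet, spec: ModelSpec, cfg: ScenarioConfig, align_pulse: bool = False
) -> float:
    eps = params.epsilon if spec.has_internalization else 0.0
    fastest = max(params.beta + params.gamma, params.delta + eps, 1e-12)
    h = min(cfg.report_interval, 0.5 / fastest)
    tau = _effective_tau(params, spec)
    if tau > 0.0:
        h = min(h, tau)
    if align_pulse:
        h = cfg.pulse_length / math.ceil(cfg.pulse_length / h - 1e-9)
    return h


def _run_segment(
    params: ParameterSet,
    spec: ModelSpec,
    h: float,
    t0: float,
    n_steps: int,
    I0: float,
    X0: float,
    hist_times: np.ndarray | None,
    hist_I: np.ndarray | None,
    phase: Phase,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate one discontinuity-free segment; returns absolute-time arrays."""
    if phase is Phase.CHASE:
        if spec.has_production_decay and params.kappa * h <= 30.0:
            alpha, kappa, mode = params.alpha, params.kappa, 1
        else:
            # no production decay, or decay so fast (kappa*h > 30, i.e. the
            # labeled pool e-folds many times within one step) that the total
            # labeled production alpha/kappa is negligible: production is
            # exactly zero, which also makes the abrupt-stop model an exact
            # boundary point (kappa -> infinity) of the decaying one
            alpha, kappa, mode = 0.0, 0.0, 0
    else:
        alpha, kappa, mode = params.alpha, 0.0, 0
    eps = params.epsilon if spec.has_internalization else 0.0
    tau = _effective_tau(params, spec)

    times = t0 + h * np.arange(n_steps + 1)
    if tau > 0.0:
        dd = tau / h
        m = int(math.ceil(dd - 1e-9)) + 1
        I = np.empty(m + n_steps)
        lookback = t0 + h * (np.arange(m) - (m - 1))
        if hist_times is None or len(hist_times) == 0:
            I[:m] = 0.0
        else:
            I[:m] = np.interp(lookback, hist_times, hist_I, left=0.0)
        I[m - 1] = I0  # the segment's initial condition wins at t0
        X = np.empty(n_steps + 1)
        X[0] = X0
        status = _integrate.rk4_delay(
            I, m, X, h, dd, alpha, kappa, mode,
            params.beta, params.gamma, params.delta, eps,
        )
        I_sol = I[m - 1 :]
    else:
        I_sol = np.empty(n_steps + 1)
        X = np.empty(n_steps + 1)
        I_sol[0] = I0
        X[0] = X0
        status = _integrate.rk4_ode(
            I_sol, X, h, alpha, kappa, mode,
            params.beta, params.gamma, params.delta, eps,
        )
    if status != 0:
        raise IntegrationDivergedError(
            f"trajectory diverged in phase {phase.value} (model {spec.model_id})"
        )
    return times, I_sol, X


def _report_grid(start: float, stop: float, interval: float) -> np.ndarray:
    n = int(math.floor((stop - start) / interval + 1e-9))
    return start + interval * np.arange(n + 1)


# --------------------------------------------------------------------------
# public operations


def run_to_steady_state(
    params: ParameterSet, spec: ModelSpec, cfg: ScenarioConfig | None = None
) -> tuple[SystemState, History]:
    """Pre-simulate from an empty system until intracellular steady state.

    The criterion is the first grid time t >= ``ss_window`` at which
    |I(t) - I(t - window)| <= ``ss_rel_change`` * I(t - window) (satisfied
    trivially when both values are zero).  Raises :class:`ConvergenceError`
    if the criterion is not met within ``presim_cap`` hours.
    """
    cfg = cfg or ScenarioConfig()
    h = _choose_step(params, spec, cfg)
    w = max(1, int(round(cfg.ss_window / h)))
    chunk_steps = max(2 * w, int(round(40.0 / h)))

    times_all = np.zeros(1)
    I_all = np.zeros(1)
    X_all = np.zeros(1)
    checked = 0
    while times_all[-1] < cfg.presim_cap:
        t0 = times_all[-1]
        times, I_seg, X_seg = _run_segment(
            params, spec, h, t0, chunk_steps, I_all[-1], X_all[-1],
            times_all, I_all, Phase.PRESIM,
        )
        times_all = np.concatenate([times_all, times[1:]])
        I_all = np.concatenate([I_all, I_seg[1:]])
        X_all = np.concatenate([X_all, X_seg[1:]])

        start = max(w, checked)
        if start < len(I_all):
            past = I_all[start - w : len(I_all) - w]
            now = I_all[start:]
            hit = np.flatnonzero(np.abs(now - past) <= cfg.ss_rel_change * past)
            if hit.size:
                idx = start + hit[0]
                state = SystemState(I=I_all[idx], X=X_all[idx], t=times_all[idx])
                hist = History(times_all[: idx + 1], I_all[: idx + 1])
                return state, hist
            checked = len(I_all)
    raise ConvergenceError(
        f"intracellular steady state not reached within {cfg.presim_cap} h "
        f"(model {spec.model_id}); long delays can prevent convergence"
    )


def integrate_segment(
    params: ParameterSet,
    spec: ModelSpec,
    init: SystemState,
    history_fn: Callable[[np.ndarray], np.ndarray] | None,
    t_span: tuple[float, float],
    phase: Phase | str,
    cfg: ScenarioConfig | None = None,
) -> Trajectory:
    """Integrate a single discontinuity-free segment and report it on the grid.

    ``history_fn`` must cover [t0 - tau, t0] for delayed models; ``None``
    means a zero pre-history.  The chase-phase production clock starts at the
    segment start (the media change).
    """
    cfg = cfg or ScenarioConfig()
    phase = Phase(phase)
    t0, t1 = t_span
    if t1 <= t0:
        raise ValueError("t_span must have t1 > t0")
    h = _choose_step(params, spec, cfg)
    tau = _effective_tau(params, spec)
    hist_times = hist_I = None
    if tau > 0.0 and history_fn is not None:
        # sample on the integrator's own lookback grid; the earliest slot can
        # precede t0 - tau by less than one step, so clamp the evaluation time
        m = int(math.ceil(tau / h - 1e-9)) + 1
        hist_times = t0 + h * (np.arange(m) - (m - 1))
        hist_I = np.asarray(history_fn(np.maximum(hist_times, t0 - tau)), dtype=float)
        if hist_I.shape != hist_times.shape or not np.all(np.isfinite(hist_I)):
            raise ValueError("history_fn must return finite values on the lookback window")
    # the chase kernel measures its production-decay clock from the segment
    # start, which by protocol is the media change
    n_steps = int(math.ceil((t1 - t0) / h - 1e-9))
    times, I_sol, X_sol = _run_segment(
        params, spec, h, t0, n_steps, init.I, init.X, hist_times, hist_I, phase
    )
    grid = _report_grid(t0, t1, cfg.report_interval)
    I_r = np.interp(grid, times, I_sol)
    X_r = np.interp(grid, times, X_sol)
    if tau > 0.0:
        full_t = times if hist_times is None else np.concatenate([hist_times[:-1], times])
        full_I = I_sol if hist_times is None else np.concatenate([hist_I[:-1], I_sol])
        I_d = np.interp(grid - tau, full_t, full_I, left=0.0)
    else:
        I_d = I_r.copy()
    return Trajectory(
        times=grid,
        I=I_r,
        X=X_r,
        phase=np.full(grid.shape, phase.value, dtype=object),
        I_delayed=I_d,
        scenario=phase.value,
        params=params,
        spec=spec,
    )


def simulate_constitutive(
    params: ParameterSet,
    spec: ModelSpec,
    cfg: ScenarioConfig | None = None,
    presim_params: ParameterSet | None = None,
) -> Trajectory:
    """Full constitutive-secretion protocol: presim, media change, 24-72 h.

    ``presim_params`` lets the pre-simulation run under different parameters
    than the reported experiment (used for acute chemical inhibition, where
    the system equilibrates at baseline before the inhibitor is applied at
    the media change).
    """
    cfg = cfg or ScenarioConfig()
    state, hist = run_to_steady_state(presim_params or params, spec, cfg)

    h = _choose_step(params, spec, cfg)
    n_steps = int(math.ceil(cfg.duration / h - 1e-9))
    hist_times = hist.times - state.t  # media change becomes t = 0
    times, I_sol, X_sol = _run_segment(
        params, spec, h, 0.0, n_steps, state.I, 0.0, hist_times, hist.I,
        Phase.CONSTITUTIVE,
    )
    grid = _report_grid(0.0, cfg.duration, cfg.report_interval)
    I_r = np.interp(grid, times, I_sol)
    X_r = np.interp(grid, times, X_sol)
    tau = _effective_tau(params, spec)
    if tau > 0.0:
        full_t = np.concatenate([hist_times[:-1], times])
        full_I = np.concatenate([hist.I[:-1], I_sol])
        I_d = np.interp(grid - tau, full_t, full_I, left=0.0)
    else:
        I_d = I_r.copy()
    return Trajectory(
        times=grid,
        I=I_r,
        X=X_r,
        phase=np.full(grid.shape, Phase.CONSTITUTIVE.value, dtype=object),
        I_delayed=I_d,
        scenario="constitutive",
        params=params,
        spec=spec,
    )


def simulate_pulse_chase(
    params: ParameterSet, spec: ModelSpec, cfg: ScenarioConfig | None = None
) -> Trajectory:
    """Pulse-chase protocol tracking labeled sFLT1 only.

    Time is on the chase clock: the pulse occupies [-pulse_length, 0) and the
    chase [0, duration].  At t=0 the media change resets X to zero while I is
    carried over, and labeled production switches off (or starts decaying).
    """
    cfg = cfg or ScenarioConfig(duration=10.0)
    h = _choose_step(params, spec, cfg, align_pulse=True)
    n_pulse = int(round(cfg.pulse_length / h))
    t_p, I_p, X_p = _run_segment(
        params, spec, h, -cfg.pulse_length, n_pulse, 0.0, 0.0, None, None, Phase.PULSE
    )
    n_chase = int(math.ceil(cfg.duration / h - 1e-9))
    t_c, I_c, X_c = _run_segment(
        params, spec, h, 0.0, n_chase, I_p[-1], 0.0, t_p, I_p, Phase.CHASE
    )

    grid_p = _report_grid(-cfg.pulse_length, 0.0, cfg.report_interval)[:-1]
    grid_c = _report_grid(0.0, cfg.duration, cfg.report_interval)
    grid = np.concatenate([grid_p, grid_c])
    I_r = np.concatenate([np.interp(grid_p, t_p, I_p), np.interp(grid_c, t_c, I_c)])
    X_r = np.concatenate([np.interp(grid_p, t_p, X_p), np.interp(grid_c, t_c, X_c)])
    phase = np.where(grid < 0.0, Phase.PULSE.value, Phase.CHASE.value).astype(object)
    tau = _effective_tau(params, spec)
    if tau > 0.0:
        full_t = np.concatenate([t_p[:-1], t_c])
        full_I = np.concatenate([I_p[:-1], I_c])
        I_d = np.interp(grid - tau, full_t, full_I, left=0.0)
    else:
        I_d = I_r.copy()
    return Trajectory(
        times=grid,
        I=I_r,
        X=X_r,
        phase=phase,
        I_delayed=I_d,
        scenario="pulse_chase",
        params=params,
        spec=spec,
    )


def normalize_trajectory(
    traj: Trajectory, anchor_X: float, anchor_I: float
) -> Trajectory:
    """Rescale to relative units: X by X(anchor_X), I by I(anchor_I)."""
    x_ref = float(traj.value_at("X", anchor_X))
    i_ref = float(traj.value_at("I", anchor_I))
    if x_ref <= 0 or i_ref <= 0:
        raise ValueError("anchor values must be positive for normalization")
    return Trajectory(
        times=traj.times,
        I=traj.I / i_ref,
        X=traj.X / x_ref,
        phase=traj.phase,
        I_delayed=traj.I_delayed / i_ref,
        scenario=traj.scenario,
        params=traj.params,
        spec=traj.spec,
        units="relative",
    )
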