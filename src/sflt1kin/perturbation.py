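"""Chemical and genetic inhibition of trafficking processes, and inversion of
observed fold changes into effective inhibition fractions.

An inhibitor reduces one process parameter p to p' = (1 - f) * p, where f in
[0, 1] is the fractional inhibition.  The two modes differ only in timing:

* **chemical** (acute) — the system pre-equilibrates at baseline parameters;
  the reduced parameter applies from the media change at t = 0 onward;
* **genetic** (chronic, e.g. siRNA days before the experiment) — the reduced
  parameter applies throughout, including the pre-simulation, so the system
  starts the experiment already at the inhibited steady state.

Given an experimentally observed fold change of intracellular or
extracellular sFLT1 relative to untreated control at some time (typically
18 h or 72 h), ``invert_inhibition`` finds the f that reproduces it.  The
simulated response is monotone in f for every target in this model class, so
the solver performs a monotonicity pre-scan followed by bisection; observed
changes beyond the f = 1 ceiling, or in the direction the model cannot
produce at any f, yield explicit infeasibility verdicts instead of a number
(the model cannot explain such measurements, which is itself informative).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import CompoundConstants, ModelSpec, ParameterSet, params_from_beta
from .simulate import ScenarioConfig, Trajectory, simulate_constitutive

__all__ = [
    "InhibitionSpec",
    "FoldChangeObservation",
    "InversionResult",
    "NonMonotoneResponseError",
    "apply_inhibition",
    "simulate_inhibited",
    "fold_changes",
    "invert_inhibition",
    "inhibition_scan",
]

TARGETS = ("alpha", "beta", "gamma", "delta", "tau")
MODES = ("chemical", "genetic")

VERDICT_OK = "ok"
VERDICT_CEILING = "infeasible: exceeds full inhibition"
VERDICT_DIRECTION = "infeasible: wrong direction"


class NonMonotoneResponseError(RuntimeError):
    """The simulated fold change is not monotone in f; bisection would lie."""


@dataclass(frozen=True)
class InhibitionSpec:
    target: str
    fraction: float
    mode: str = "chemical"

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}, got {self.target!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction inhibition must be in [0, 1]")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class FoldChangeObservation:
    species: str  # "I" or "X"
    time_h: float  # typically 18 or 72
    fold_change: float  # treated / control, > 0

    def __post_init__(self) -> None:
        if self.species not in ("I", "X"):
            raise ValueError("species must be 'I' or 'X'")
        if self.fold_change <= 0:
            raise ValueError("fold change must be > 0")


@dataclass(frozen=True)
class InversionResult:
    verdict: str
    fraction: float | None  # estimated f when verdict == "ok"
    observed: FoldChangeObservation
    target: str
    mode: str
    ceiling_fold_change: float  # simulated fold change at f = 1

    @property
    def feasible(self) -> bool:
        return self.verdict == VERDICT_OK


def apply_inhibition(params: ParameterSet, inh: InhibitionSpec) -> ParameterSet:
    value = getattr(params, inh.target)
    return replace(params, **{inh.target: (1.0 - inh.fraction) * value})


def simulate_inhibited(
    params: ParameterSet,
    spec: ModelSpec,
    inh: InhibitionSpec,
    cfg: ScenarioConfig | None = None,
) -> Trajectory:
    """Constitutive protocol under inhibition (see module docstring for modes)."""
    inhibited = apply_inhibition(params, inh)
    if inh.mode == "chemical":
        return simulate_constitutive(inhibited, spec, cfg, presim_params=params)
    return simulate_constitutive(inhibited, spec, cfg)


def fold_changes(
    inhibited: Trajectory,
    control: Trajectory,
    times: Sequence[float] = (18.0, 72.0),
    species: Sequence[str] = ("I", "X"),
) -> pd.DataFrame:
    """Treated/control ratios per species and time, with log2 columns."""
    rows = []
    for sp in species:
        for t in times:
            ref = float(control.value_at(sp, t))
            if ref <= 0:
                raise ValueError(f"control {sp} is zero at {t} h; fold change undefined")
            fc = float(inhibited.value_at(sp, t)) / ref
            rows.append(
                {
                    "species": sp,
                    "time_h": t,
                    "fold_change": fc,
                    "log2_fold_change": np.log2(fc) if fc > 0 else -np.inf,
                }
            )
    return pd.DataFrame(rows)


def _response(
    f: float,
    target: str,
    mode: str,
    params: ParameterSet,
    spec: ModelSpec,
    control: Trajectory,
    observed: FoldChangeObservation,
    cfg: ScenarioConfig,
) -> float:
    inh = InhibitionSpec(target=target, fraction=f, mode=mode)
    traj = simulate_inhibited(params, spec, inh, cfg)
    ref = float(control.value_at(observed.species, observed.time_h))
    return float(traj.value_at(observed.species, observed.time_h)) / ref


def invert_inhibition(
    observed: FoldChangeObservation,
    target: str,
    mode: str,
    params: ParameterSet,
    spec: ModelSpec,
    tol: float = 1.0e-3,
    prescan_points: int = 21,
) -> InversionResult:
    """Find the fractional inhibition f reproducing an observed fold change.

    Solves on the fold-change (not log) scale by bisection after a
    monotonicity pre-scan; returns an infeasibility verdict when no f in
    [0, 1] can reach the observation."""
    cfg = ScenarioConfig(duration=max(observed.time_h, 1.0))
    control = simulate_constitutive(params, spec, cfg)

    grid = np.linspace(0.0, 1.0, prescan_points)
    values = np.array(
        [_response(f, target, mode, params, spec, control, observed, cfg) for f in grid]
    )
    diffs = np.diff(values)
    flat_tol = 1e-9 * max(1.0, np.abs(values).max())
    rising = diffs > flat_tol
    falling = diffs < -flat_tol
    if rising.any() and falling.any():
        raise NonMonotoneResponseError(
            f"fold change of {observed.species} under {mode} {target} inhibition "
            "is not monotone in f; bisection is not applicable"
        )

    ceiling = float(values[-1])
    y = observed.fold_change
    direction = 1.0 if ceiling >= values[0] else -1.0
    # values[0] is the uninhibited case (fold change 1 up to numerics)
    if direction * (y - values[0]) < 0 and not np.isclose(y, values[0], rtol=1e-6):
        return InversionResult(VERDICT_DIRECTION, None, observed, target, mode, ceiling)
    if direction * (y - ceiling) > 0:
        return InversionResult(VERDICT_CEILING, None, observed, target, mode, ceiling)

    # locate bracketing grid cell, then bisect to |df| <= tol
    idx = 0
    for i in range(len(grid) - 1):
        lo_v, hi_v = values[i], values[i + 1]
        if min(lo_v, hi_v) - 1e-12 <= y <= max(lo_v, hi_v) + 1e-12:
            idx = i
            break
    lo, hi = float(grid[idx]), float(grid[idx + 1])
    v_lo = float(values[idx])
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        v_mid = _response(mid, target, mode, params, spec, control, observed, cfg)
        if (v_mid - y) * (v_lo - y) <= 0:
            hi = mid
        else:
            lo, v_lo = mid, v_mid
    return InversionResult(VERDICT_OK, 0.5 * (lo + hi), observed, target, mode, ceiling)


def inhibition_scan(
    constants: CompoundConstants,
    delta: float,
    tau: float,
    spec: ModelSpec,
    beta_fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    targets: Sequence[str] = ("alpha", "beta", "gamma", "delta"),
    f_grid: Sequence[float] | None = None,
    times: Sequence[float] = (18.0, 72.0),
    modes: Sequence[str] = ("chemical", "genetic"),
) -> pd.DataFrame:
    """Fold-change surfaces across the one-parameter family of baselines.

    Baselines are built from the (c1, c2) constraints by setting beta to the
    given fractions of c2 (alpha = c1/beta, gamma = c2 - beta), so the scan
    shows how inhibition predictions depend on the residual degree of
    freedom left by the time-course data."""
    f_grid = np.linspace(0.0, 1.0, 11) if f_grid is None else np.asarray(f_grid)
    cfg = ScenarioConfig(duration=max(times))
    rows = []
    for frac in beta_fractions:
        baseline = params_from_beta(frac * constants.c2, constants, delta, tau)
        baseline = baseline.restricted_to(spec)
        control = simulate_constitutive(baseline, spec, cfg)
        for mode in modes:
            for target in targets:
                for f in f_grid:
                    inh = InhibitionSpec(target=target, fraction=float(f), mode=mode)
                    traj = simulate_inhibited(baseline, spec, inh, cfg)
                    fc = fold_changes(traj, control, times=times)
                    fc.insert(0, "beta_fraction_of_c2", frac)
                    fc.insert(1, "mode", mode)
                    fc.insert(2, "target", target)
                    fc.insert(3, "fraction_inhibition", float(f))
                    rows.append(fc)
    return pd.concat(rows, ignore_index=True)
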