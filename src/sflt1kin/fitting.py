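"""Multistart nonlinear least-squares fitting of candidate models to datasets.

The cost function is the unweighted sum of squared *relative* errors,
(simulated - observed) / observed, across every included observation of every
dataset, with each dataset simulated under its own scenario (constitutive or
pulse-chase) and converted to its own measurement units before comparison.

Optimization is bounded trust-region-reflective least squares on the residual
vector, run from many initial guesses sampled log-uniformly across wide,
biologically motivated ranges (parameter priors span orders of magnitude, as
typical for protein synthesis/trafficking/degradation rates).  Rate constants
with strictly positive bounds are optimized on a log10 scale, which keeps the
search well-conditioned across those ranges; the delay and the two optional
process parameters are optimized on a linear scale so that the boundary of a
nested (process-absent) model is reachable.  Starts whose trial trajectories
diverge or fail to pre-equilibrate return a large constant penalty residual,
so the optimizer retreats rather than crashing.

An ensemble is summarized by its *accepted* subset: fits whose cost is within
``filter_rel`` (default 10%) of the minimum.  A small absolute floor is added
to the threshold so that on noiseless data, where costs at the optimum are
dominated by solver round-off scatter many orders of magnitude below any
measurable misfit, equally perfect fits are not spuriously rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data_io import ExperimentalDataset, predict_in_dataset_units, preprocess
from .model_core import (
    CompoundConstants,
    ModelSpec,
    ParameterSet,
    compound_constants,
)
from .simulate import (
    ConvergenceError,
    IntegrationDivergedError,
    ScenarioConfig,
    simulate_constitutive,
    simulate_pulse_chase,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "FitEnsemble",
    "DEFAULT_SAMPLING_RANGES",
    "DEFAULT_BOUNDS",
    "residuals",
    "sample_initial_guesses",
    "fit_multistart",
    "summarize_ensemble",
]

#: Residual value substituted when a trial point cannot be simulated.
PENALTY = 1.0e3

DEFAULT_SAMPLING_RANGES: dict[str, tuple[float, float]] = {
    "alpha": (1.0e3, 1.0e7),
    "beta": (1.0e-4, 10.0),
    "gamma": (1.0e-4, 10.0),
    "delta": (1.0e-4, 10.0),
    "tau": (0.0, 8.0),
    "epsilon": (1.0e-3, 10.0),
    "kappa": (1.0e-2, 1.0e2),
}

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (1.0e3, 1.0e7),
    "beta": (1.0e-4, 10.0),
    "gamma": (1.0e-4, 10.0),
    "delta": (1.0e-4, 10.0),
    "tau": (0.0, 8.0),
    "epsilon": (0.0, 10.0),
    "kappa": (0.0, 1.0e4),
}


@dataclass(frozen=True)
class FitConfig:
    """Multistart settings; ranges/bounds are overridable per parameter."""

    n_starts: int = 50
    seed: int = 0
    filter_rel: float = 0.10
    cost_floor: float = 1.0e-6
    sampling_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLING_RANGES)
    )
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    ftol: float = 1.0e-8
    xtol: float = 1.0e-8
    max_nfev: int = 400
    diff_step: float = 1.0e-4

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for name, (lo, hi) in {**self.sampling_ranges, **self.bounds}.items():
            if lo > hi:
                raise ValueError(f"range for {name} has low > high")


@dataclass(frozen=True)
class FitResult:
    params: ParameterSet
    cost: float
    per_dataset_cost: dict[str, float]
    converged: bool
    start_params: ParameterSet


@dataclass
class FitEnsemble:
    spec: ModelSpec
    config: FitConfig
    results: list[FitResult]
    accepted: list[FitResult]

    @property
    def best(self) -> FitResult:
        converged = [r for r in self.results if r.converged]
        pool = converged or self.results
        return min(pool, key=lambda r: r.cost)

    @property
    def min_cost(self) -> float:
        return self.best.cost

    def to_frame(self) -> pd.DataFrame:
        accepted_ids = {id(r) for r in self.accepted}
        rows = []
        for r in self.results:
            row: dict[str, object] = {
                f"start_{k}": v for k, v in r.start_params.as_dict().items()
            }
            row.update(r.params.as_dict())
            row["cost"] = r.cost
            row["converged"] = r.converged
            row["accepted"] = id(r) in accepted_ids
            for name, c in r.per_dataset_cost.items():
                row[f"cost_{name}"] = c
            rows.append(row)
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# residuals


class _FitProblem:
    """Pre-compiled observation arrays for fast repeated residual evaluation."""

    def __init__(
        self,
        spec: ModelSpec,
        datasets: Sequence[ExperimentalDataset],
        cfg: FitConfig,
    ):
        self.spec = spec
        self.cfg = cfg
        self.datasets = list(datasets)
        self.free_names = list(spec.active_parameters())
        self.log_mask = np.array(
            [cfg.bounds[n][0] > 0 for n in self.free_names], dtype=bool
        )
        lo = np.array([cfg.bounds[n][0] for n in self.free_names])
        hi = np.array([cfg.bounds[n][1] for n in self.free_names])
        self.lo_t = np.where(self.log_mask, np.log10(np.where(lo > 0, lo, 1.0)), lo)
        self.hi_t = np.where(self.log_mask, np.log10(hi), hi)

        self.scenarios: set[str] = set()
        self.durations: dict[str, float] = {}
        self.obs: list[dict] = []
        self.slices: list[slice] = []
        offset = 0
        for ds in self.datasets:
            included = ds.included()
            if (included["value"] <= 0).any():
                raise ValueError(
                    f"dataset {ds.name!r} has zero-valued observations; relative "
                    "error is undefined (exclude them or use different units)"
                )
            self.scenarios.add(ds.scenario)
            t_need = float(included["time_h"].max())
            for anchor in (ds.anchor_time_X, ds.anchor_time_I):
                if anchor is not None:
                    t_need = max(t_need, float(anchor))
            self.durations[ds.scenario] = max(
                self.durations.get(ds.scenario, 0.0), t_need
            )
            n = len(included)
            self.obs.append({"dataset": ds, "values": included["value"].to_numpy()})
            self.slices.append(slice(offset, offset + n))
            offset += n
        self.n_obs = offset

    def to_vector(self, params: ParameterSet) -> np.ndarray:
        raw = np.array([getattr(params, n) for n in self.free_names])
        x = np.where(self.log_mask, np.log10(np.maximum(raw, 1e-300)), raw)
        return np.clip(x, self.lo_t, self.hi_t)

    def from_vector(self, x: np.ndarray) -> ParameterSet:
        raw = np.asarray(x, dtype=float).copy()
        raw[self.log_mask] = 10.0 ** raw[self.log_mask]
        values = dict(zip(self.free_names, (float(v) for v in raw)))
        return ParameterSet(**values)

    def _trajectories(self, params: ParameterSet):
        trajs = {}
        if "constitutive" in self.scenarios:
            trajs["constitutive"] = simulate_constitutive(
                params, self.spec, ScenarioConfig(duration=self.durations["constitutive"])
            )
        if "pulse_chase" in self.scenarios:
            trajs["pulse_chase"] = simulate_pulse_chase(
                params, self.spec, ScenarioConfig(duration=self.durations["pulse_chase"])
            )
        return trajs

    def residuals_params(self, params: ParameterSet) -> np.ndarray:
        try:
            trajs = self._trajectories(params)
            out = np.empty(self.n_obs)
            for entry, sl in zip(self.obs, self.slices):
                ds = entry["dataset"]
                pred = predict_in_dataset_units(trajs[ds.scenario], ds)
                # predict_in_dataset_units preserves included-row order within
                # species groups sorted alphabetically, matching ds.included()
                # after preprocessing (sorted by species, time)
                p = pred["predicted"].to_numpy()
                e = entry["values"]
                if ds.free_scale:
                    ratio = p / e
                    denom = float(ratio @ ratio)
                    scale = ratio.sum() / denom if denom > 0 else 1.0
                    out[sl] = scale * ratio - 1.0
                else:
                    out[sl] = (p - e) / e
            if not np.all(np.isfinite(out)):
                return np.full(self.n_obs, PENALTY)
            return out
        except (ConvergenceError, IntegrationDivergedError):
            return np.full(self.n_obs, PENALTY)

    def residuals_vector(self, x: np.ndarray) -> np.ndarray:
        return self.residuals_params(self.from_vector(x))

    def per_dataset_cost(self, res: np.ndarray) -> dict[str, float]:
        return {
            entry["dataset"].name: float(np.sum(res[sl] ** 2))
            for entry, sl in zip(self.obs, self.slices)
        }


def residuals(
    params: ParameterSet,
    spec: ModelSpec,
    datasets: Sequence[ExperimentalDataset],
    cfg: FitConfig | None = None,
) -> np.ndarray:
    """Relative-error residual vector (one entry per included observation)."""
    problem = _FitProblem(spec, [preprocess(d) for d in datasets], cfg or FitConfig())
    return problem.residuals_params(params)


# --------------------------------------------------------------------------
# multistart


def sample_initial_guesses(
    cfg: FitConfig, spec: ModelSpec, rng: np.random.Generator | None = None
) -> list[ParameterSet]:
    """Reproducible initial guesses, log-uniform across each sampling range
    (uniform for ranges that include zero)."""
    rng = rng or np.random.default_rng(cfg.seed)
    names = spec.active_parameters()
    guesses = []
    for _ in range(cfg.n_starts):
        values = {}
        for name in names:
            lo, hi = cfg.sampling_ranges[name]
            if lo > 0:
                values[name] = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi))
            else:
                values[name] = rng.uniform(lo, hi)
        guesses.append(ParameterSet(**values))
    return guesses


def fit_multistart(
    spec: ModelSpec,
    datasets: Sequence[ExperimentalDataset],
    cfg: FitConfig | None = None,
    extra_starts: Iterable[ParameterSet] = (),
) -> FitEnsemble:
    """Bounded least squares from each sampled start; failed starts are
    recorded, not fatal.  The accepted subset collects fits within
    ``filter_rel`` of the minimum cost (plus the ``cost_floor`` slack)."""
    cfg = cfg or FitConfig()
    datasets = [preprocess(d) for d in datasets]
    problem = _FitProblem(spec, datasets, cfg)
    starts = sample_initial_guesses(cfg, spec) + [
        s.restricted_to(spec) for s in extra_starts
    ]

    results: list[FitResult] = []
    for start in starts:
        x0 = problem.to_vector(start)
        try:
            sol = least_squares(
                problem.residuals_vector,
                x0,
                bounds=(problem.lo_t, problem.hi_t),
                method="trf",
                ftol=cfg.ftol,
                xtol=cfg.xtol,
                diff_step=cfg.diff_step,
                max_nfev=cfg.max_nfev,
            )
            params = problem.from_vector(sol.x)
            res = sol.fun
            cost = float(res @ res)
            converged = bool(sol.success) and not np.any(res == PENALTY)
        except Exception:
            params = start
            cost = float("inf")
            res = np.full(problem.n_obs, PENALTY)
            converged = False
        results.append(
            FitResult(
                params=params,
                cost=cost,
                per_dataset_cost=problem.per_dataset_cost(res),
                converged=converged,
                start_params=start,
            )
        )

    converged = [r for r in results if r.converged]
    if converged:
        min_cost = min(r.cost for r in converged)
        threshold = max((1.0 + cfg.filter_rel) * min_cost, min_cost + cfg.cost_floor)
        accepted = [r for r in converged if r.cost <= threshold]
    else:
        accepted = []
    return FitEnsemble(spec=spec, config=cfg, results=results, accepted=accepted)


def summarize_ensemble(ensemble: FitEnsemble) -> pd.DataFrame:
    """Distribution statistics of the accepted fits, per kinetic parameter and
    per compound constant (c1 = alpha*beta, c2 = beta+gamma)."""
    if not ensemble.accepted:
        raise ValueError("ensemble has no accepted fits to summarize")
    names = list(ensemble.spec.active_parameters())
    data = {n: np.array([getattr(r.params, n) for r in ensemble.accepted]) for n in names}
    data["c1"] = np.array(
        [compound_constants(r.params).c1 for r in ensemble.accepted]
    )
    data["c2"] = np.array(
        [compound_constants(r.params).c2 for r in ensemble.accepted]
    )
    stats = {}
    for name, vals in data.items():
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        med = float(np.median(vals))
        stats[name] = {
            "mean": mean,
            "sd": sd,
            "cv": sd / mean if mean != 0 else float("nan"),
            "median": med,
            "mad": float(np.median(np.abs(vals - med))),
            "iqr": float(np.percentile(vals, 75) - np.percentile(vals, 25)),
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
        }
    return pd.DataFrame(stats)
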