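"""Scoring and comparison of the eight candidate models by cost and AICc.

Each candidate is fit by multistart least squares to the same datasets and
scored with the small-sample corrected Akaike Information Criterion

    AICc = n * ln(C / n) + 2k + 2k(k+1) / (n - k - 1)

where ``n`` is the number of observations, ``C`` the minimized cost and ``k``
the degrees of freedom (active parameter count + 1).  Natural log is used;
since AICc enters only through rank order and differences, the base is a
convention.  Because residuals are relative errors, the ranking is invariant
to rescaling all data and predictions by a common positive factor.

Nested warm starts: besides its own random starts, each model is started
from the best fit of every sub-model with one process fewer, placing the new
process parameter at its "absent" boundary (tau = 0 or epsilon = 0; kappa at
its upper bound, since production decay reduces to an abrupt production stop
as kappa grows large).  This guarantees, up to solver tolerance, that adding
a process never increases the best attainable cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import log
from typing import Sequence

import pandas as pd

from .data_io import ExperimentalDataset, preprocess
from .fitting import DEFAULT_BOUNDS, FitConfig, FitEnsemble, fit_multistart
from .model_core import ModelSpec, ParameterSet, all_model_specs

__all__ = ["ModelScore", "aicc", "compare_models", "scores_to_frame"]

_PROCESS_FLAGS = {
    "tau": "has_delay",
    "epsilon": "has_internalization",
    "kappa": "has_production_decay",
}


def aicc(C: float, n: int, k: int) -> float:
    """Corrected Akaike Information Criterion for a least-squares fit."""
    if C <= 0:
        raise ValueError("cost must be > 0 (a zero cost makes the score degenerate)")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n = {n} <= k + 1 = {k + 1}")
    return n * log(C / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class ModelScore:
    model_id: str
    spec: ModelSpec
    k: int  # degrees of freedom: active parameters + 1
    n: int  # observation count
    min_cost: float
    aicc: float
    per_dataset_cost: dict[str, float]
    best_params: ParameterSet


@dataclass
class ModelComparison:
    scores: list[ModelScore]
    edges: pd.DataFrame  # one row per (model, addable process): cost reduction
    ensembles: dict[str, FitEnsemble]

    @property
    def ranked(self) -> list[ModelScore]:
        return sorted(self.scores, key=lambda s: s.aicc)

    @property
    def best_model(self) -> ModelScore:
        return self.ranked[0]


def _sub_specs(spec: ModelSpec) -> list[tuple[str, ModelSpec]]:
    """(removed process, sub-model) pairs with exactly one process fewer."""
    subs = []
    for param, flag in _PROCESS_FLAGS.items():
        if getattr(spec, flag):
            subs.append((param, replace(spec, **{flag: False})))
    return subs


def _boundary_value(param: str, cfg: FitConfig) -> float:
    # kappa -> infinity recovers the abrupt-stop model; use the upper bound
    if param == "kappa":
        return cfg.bounds.get("kappa", DEFAULT_BOUNDS["kappa"])[1]
    return 0.0


def compare_models(
    datasets: Sequence[ExperimentalDataset],
    cfg: FitConfig | None = None,
    specs: Sequence[ModelSpec] | None = None,
    warm_start: bool = True,
) -> ModelComparison:
    """Fit every candidate model to the same datasets and score by AICc.

    Models are processed in order of increasing complexity so nested warm
    starts (see module docstring) are available; per-(model, process) cost
    reductions are tabulated as graph edges for a cost-vs-complexity view.
    """
    cfg = cfg or FitConfig()
    datasets = [preprocess(d) for d in datasets]
    specs = list(specs) if specs is not None else all_model_specs()
    specs.sort(key=lambda s: s.n_processes)

    n_obs = sum(d.n_observations for d in datasets)
    ensembles: dict[str, FitEnsemble] = {}
    scores: dict[str, ModelScore] = {}
    for spec in specs:
        extra: list[ParameterSet] = []
        if warm_start:
            for param, sub in _sub_specs(spec):
                if sub.model_id in scores:
                    base = scores[sub.model_id].best_params
                    extra.append(
                        replace(base, **{param: _boundary_value(param, cfg)})
                    )
        ensemble = fit_multistart(spec, datasets, cfg, extra_starts=extra)
        best = ensemble.best
        ensembles[spec.model_id] = ensemble
        scores[spec.model_id] = ModelScore(
            model_id=spec.model_id,
            spec=spec,
            k=spec.k_dof,
            n=n_obs,
            min_cost=best.cost,
            aicc=aicc(best.cost, n_obs, spec.k_dof),
            per_dataset_cost=best.per_dataset_cost,
            best_params=best.params,
        )

    edge_rows = []
    for spec in specs:
        for param, flag in _PROCESS_FLAGS.items():
            if getattr(spec, flag):
                continue
            larger = replace(spec, **{flag: True})
            if larger.model_id in scores and spec.model_id in scores:
                edge_rows.append(
                    {
                        "from_model": spec.model_id,
                        "to_model": larger.model_id,
                        "added_process": param,
                        "cost_reduction": scores[spec.model_id].min_cost
                        - scores[larger.model_id].min_cost,
                    }
                )
    return ModelComparison(
        scores=[scores[s.model_id] for s in specs],
        edges=pd.DataFrame(edge_rows),
        ensembles=ensembles,
    )


def scores_to_frame(comparison: ModelComparison) -> pd.DataFrame:
    """Comparison table: processes present, cost by dataset, AICc."""
    rows = []
    for s in comparison.scores:
        row: dict[str, object] = {
            "model": s.model_id,
            "delay": s.spec.has_delay,
            "internalization": s.spec.has_internalization,
            "production_decay": s.spec.has_production_decay,
            "k": s.k,
            "n": s.n,
            "cost": s.min_cost,
            "aicc": s.aicc,
        }
        for name, c in s.per_dataset_cost.items():
            row[f"cost_{name}"] = c
        rows.append(row)
    return pd.DataFrame(rows)
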