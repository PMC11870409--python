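"""Synthetic datasets with the statistical structure of the three study designs.

Real time-course measurements of sFLT1 secretion come in three flavors:

* ``hornig_like`` — constitutive secretion, extracellular only, absolute
  concentration units (an ELISA of conditioned media);
* ``kinghorn_like`` — constitutive secretion, extracellular + intracellular,
  relative units normalized at anchor times (quantitative Western blots),
  out to 72 h;
* ``jung_like`` — pulse-chase, extracellular + intracellular, relative
  units, 20-minute pulse and a chase of up to 10 h.

The generator simulates the design's scenario from known parameters, samples
the trajectory at the design's time grid, converts to the design's units and
applies per-replicate multiplicative lognormal noise of a given coefficient
of variation (immunoassay and densitometry errors are approximately
proportional to signal).  Each default grid carries one pre-flagged excluded
point, so the full preprocessing path (exclusion, replicate averaging) is
exercised end to end.  Observations whose noiseless value is zero (e.g.
extracellular protein at the media change, or before any labeled protein has
matured) are omitted: they are below any assay's limit of quantitation and
relative error is undefined for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ExperimentalDataset, UnitConversion, preprocess
from .fitting import FitConfig, FitEnsemble, fit_multistart, summarize_ensemble
from .model_core import ModelSpec, ParameterSet, compound_constants
from .simulate import ScenarioConfig, simulate_constitutive, simulate_pulse_chase

__all__ = [
    "SyntheticDesign",
    "hornig_like",
    "kinghorn_like",
    "jung_like",
    "default_designs",
    "generate_dataset",
    "RecoveryReport",
    "recovery_experiment",
]


@dataclass(frozen=True)
class SyntheticDesign:
    """Measurement design: grid, species, units, noise and replication."""

    template: str
    scenario: str
    time_grid: tuple[float, ...]
    species: tuple[str, ...]
    units: str
    anchor_time_X: float | None = None
    anchor_time_I: float | None = None
    excluded_times: tuple[float, ...] = ()
    replicates: int = 3
    noise_cv: float = 0.10
    seed: int = 0
    conversion: UnitConversion = field(default_factory=UnitConversion)
    name: str | None = None

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.template == "jung_like" and self.scenario != "pulse_chase":
            raise ValueError("jung_like designs are pulse-chase by construction")


def hornig_like(noise_cv: float = 0.10, replicates: int = 3, seed: int = 0) -> SyntheticDesign:
    """Constitutive secretion, extracellular ELISA-style absolute units.

    The 3 h point is pre-flagged excluded (emulating a value below the
    assay's limit of quantitation)."""
    return SyntheticDesign(
        template="hornig_like",
        scenario="constitutive",
        time_grid=(1.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0),
        species=("X",),
        units="absolute_concentration",
        excluded_times=(3.0,),
        replicates=replicates,
        noise_cv=noise_cv,
        seed=seed,
    )


def kinghorn_like(noise_cv: float = 0.10, replicates: int = 3, seed: int = 0) -> SyntheticDesign:
    """Constitutive secretion, Western-style relative units, both species."""
    return SyntheticDesign(
        template="kinghorn_like",
        scenario="constitutive",
        time_grid=(0.0, 2.0, 4.0, 8.0, 24.0, 48.0, 72.0),
        species=("I", "X"),
        units="relative",
        anchor_time_X=24.0,
        anchor_time_I=0.0,
        replicates=replicates,
        noise_cv=noise_cv,
        seed=seed,
    )


def jung_like(noise_cv: float = 0.10, replicates: int = 3, seed: int = 0) -> SyntheticDesign:
    """Pulse-chase, relative units, both species, 10 h chase.

    The 10 h point is pre-flagged excluded (emulating a trend inconsistent
    with the rest of the time course)."""
    return SyntheticDesign(
        template="jung_like",
        scenario="pulse_chase",
        time_grid=(0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0),
        species=("I", "X"),
        units="relative",
        anchor_time_X=8.0,
        anchor_time_I=0.0,
        excluded_times=(10.0,),
        replicates=replicates,
        noise_cv=noise_cv,
        seed=seed,
    )


def default_designs(noise_cv: float = 0.10, seed: int = 0) -> list[SyntheticDesign]:
    """The three designs with distinct sub-seeds, mirroring the study mix."""
    return [
        hornig_like(noise_cv=noise_cv, seed=seed),
        kinghorn_like(noise_cv=noise_cv, seed=seed + 1),
        jung_like(noise_cv=noise_cv, seed=seed + 2),
    ]


def generate_dataset(
    params: ParameterSet,
    spec: ModelSpec,
    design: SyntheticDesign,
    rng: np.random.Generator | None = None,
) -> ExperimentalDataset:
    """Simulate the design's scenario and sample noisy observations.

    Noise is multiplicative lognormal with unit mean and coefficient of
    variation ``design.noise_cv``, drawn independently per observation and
    replicate; draws depend only on the seed, so relative-unit datasets are
    invariant to the generating production rate (the trafficking equations
    are linear in the amount of protein)."""
    params.validate_for(spec)
    rng = rng or np.random.default_rng(design.seed)
    duration = max(design.time_grid)
    if design.anchor_time_X is not None:
        duration = max(duration, design.anchor_time_X)
    cfg = ScenarioConfig(duration=duration)
    if design.scenario == "constitutive":
        traj = simulate_constitutive(params, spec, cfg)
    else:
        traj = simulate_pulse_chase(params, spec, cfg)

    cv = design.noise_cv
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    rows = []
    for species in sorted(design.species):
        clean = np.asarray(traj.value_at(species, np.asarray(design.time_grid)), float)
        if design.units == "relative":
            anchor = design.anchor_time_X if species == "X" else design.anchor_time_I
            ref = float(traj.value_at(species, anchor))
            if ref <= 0:
                raise ValueError(
                    f"anchor time {anchor} h has zero noiseless value for {species}"
                )
            clean = clean / ref
        else:
            clean = clean * design.conversion.ng_per_ml_per_molecule_per_cell
        for t, value in zip(design.time_grid, clean):
            noise = (
                np.exp(rng.normal(-0.5 * sigma * sigma, sigma, design.replicates))
                if cv > 0
                else np.ones(design.replicates)
            )
            if value <= 0.0:
                continue  # below limit of quantitation; relative error undefined
            for rep in range(design.replicates):
                rows.append(
                    {
                        "time_h": t,
                        "species": species,
                        "value": value * noise[rep],
                        "replicate": rep,
                        "excluded": t in design.excluded_times,
                    }
                )
    return ExperimentalDataset(
        name=design.name or design.template,
        scenario=design.scenario,
        observations=pd.DataFrame(rows),
        units=design.units,
        anchor_time_X=design.anchor_time_X,
        anchor_time_I=design.anchor_time_I,
        conversion=design.conversion if design.units == "absolute_concentration" else None,
    )


@dataclass
class RecoveryReport:
    """Parameter-recovery outcome: generate -> fit -> compare."""

    generating: ParameterSet
    spec: ModelSpec
    ensemble: FitEnsemble
    recovered_median: dict[str, float]
    relative_error: dict[str, float]
    compound_cv: dict[str, float]
    spread: dict[str, float]  # max/min ratio across accepted fits

    def to_frame(self) -> pd.DataFrame:
        names = sorted(self.recovered_median)
        return pd.DataFrame(
            {
                "generating": [
                    getattr(self.generating, n, None)
                    if not n.startswith("c")
                    else {
                        "c1": compound_constants(self.generating).c1,
                        "c2": compound_constants(self.generating).c2,
                    }[n]
                    for n in names
                ],
                "recovered_median": [self.recovered_median[n] for n in names],
                "relative_error": [self.relative_error.get(n) for n in names],
                "spread_max_over_min": [self.spread.get(n) for n in names],
            },
            index=names,
        )


def recovery_experiment(
    params: ParameterSet,
    spec: ModelSpec,
    designs: Sequence[SyntheticDesign],
    fit_cfg: FitConfig | None = None,
) -> RecoveryReport:
    """Generate datasets from known parameters, refit, and report how well
    parameters and compound constants are recovered and constrained."""
    params = params.restricted_to(spec)
    datasets = [preprocess(generate_dataset(params, spec, d)) for d in designs]
    ensemble = fit_multistart(spec, datasets, fit_cfg or FitConfig())
    if not ensemble.accepted:
        raise RuntimeError("no accepted fits; cannot assess recovery")
    summary = summarize_ensemble(ensemble)

    truth = params.as_dict()
    truth["c1"] = compound_constants(params).c1
    truth["c2"] = compound_constants(params).c2
    recovered, rel_err, spread = {}, {}, {}
    for name in summary.columns:
        med = float(summary.loc["median", name])
        recovered[name] = med
        if truth.get(name):
            rel_err[name] = abs(med - truth[name]) / truth[name]
        lo, hi = float(summary.loc["min", name]), float(summary.loc["max", name])
        spread[name] = hi / lo if lo > 0 else float("inf")
    compound_cv = {
        "c1": float(summary.loc["cv", "c1"]),
        "c2": float(summary.loc["cv", "c2"]),
    }
    return RecoveryReport(
        generating=params,
        spec=spec,
        ensemble=ensemble,
        recovered_median=recovered,
        relative_error=rel_err,
        compound_cv=compound_cv,
        spread=spread,
    )
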