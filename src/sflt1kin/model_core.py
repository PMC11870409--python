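"""Kinetic parameters, candidate model structures, and closed-form quantities.

The system tracks two pools of soluble FLT1 (sFLT1): intracellular protein
``I`` and extracellular (secreted) protein ``X``, both in molecules per cell
(#/cell).  The base processes are zeroth-order production (rate ``alpha``,
#/cell/h), first-order secretion I -> X (rate constant ``beta``, 1/h),
first-order intracellular degradation I -> 0 (``gamma``, 1/h) and first-order
extracellular degradation X -> 0 (``delta``, 1/h).  Three optional processes
extend the base model:

* a fixed maturation delay ``tau`` (h) applied to secretion and intracellular
  degradation, turning the ODEs into delay differential equations,
* internalization X -> I with rate constant ``epsilon`` (1/h),
* exponential decay ``alpha * exp(-kappa * t)`` of production during the chase
  phase of a pulse-chase experiment (``kappa``, 1/h), representing gradual
  washout of labeled amino acids instead of an abrupt stop.

The eight on/off combinations of the three optional processes define the
candidate models M1..M8 (M1: none of them, i.e. the plain ODE model;
M2: maturation delay only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "Phase",
    "ModelSpec",
    "ParameterSet",
    "SystemState",
    "CompoundConstants",
    "SteadyStateSummary",
    "MODEL_IDS",
    "model_from_id",
    "all_model_specs",
    "rate_terms",
    "steady_state",
    "compound_constants",
    "params_from_beta",
    "theoretical_bounds",
    "median_parameters",
    "load_parameters",
    "save_parameters",
    "DegenerateParameterError",
]

LN2 = math.log(2.0)


class DegenerateParameterError(ValueError):
    """Raised when a closed-form quantity has a vanishing denominator."""


class Phase(str, Enum):
    """Experimental phase a model segment is integrated under."""

    PRESIM = "presim"
    PULSE = "pulse"
    CHASE = "chase"
    CONSTITUTIVE = "constitutive"


@dataclass(frozen=True)
class ModelSpec:
    """Which optional processes are present; identifies candidate models M1-M8."""

    has_delay: bool = False
    has_internalization: bool = False
    has_production_decay: bool = False

    @property
    def model_id(self) -> str:
        return _FLAGS_TO_ID[
            (self.has_delay, self.has_internalization, self.has_production_decay)
        ]

    @property
    def n_processes(self) -> int:
        return sum(
            (self.has_delay, self.has_internalization, self.has_production_decay)
        )

    def active_parameters(self) -> tuple[str, ...]:
        """Names of the kinetic parameters that are free in this model."""
        names = ["alpha", "beta", "gamma", "delta"]
        if self.has_delay:
            names.append("tau")
        if self.has_internalization:
            names.append("epsilon")
        if self.has_production_decay:
            names.append("kappa")
        return tuple(names)

    @property
    def k_dof(self) -> int:
        """Degrees of freedom used in AICc scoring: parameter count + 1."""
        return len(self.active_parameters()) + 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.model_id


# M1 has no optional process and M2 adds only the maturation delay; the
# remaining labels enumerate the other flag combinations in order of
# increasing complexity (single additions, then pairs, then all three).
_ID_TO_FLAGS: dict[str, tuple[bool, bool, bool]] = {
    "M1": (False, False, False),
    "M2": (True, False, False),
    "M3": (False, True, False),
    "M4": (False, False, True),
    "M5": (True, True, False),
    "M6": (True, False, True),
    "M7": (False, True, True),
    "M8": (True, True, True),
}
_FLAGS_TO_ID = {v: k for k, v in _ID_TO_FLAGS.items()}
MODEL_IDS: tuple[str, ...] = tuple(_ID_TO_FLAGS)


def model_from_id(model_id: str) -> ModelSpec:
    try:
        flags = _ID_TO_FLAGS[model_id.upper()]
    except KeyError:
        raise ValueError(
            f"unknown model id {model_id!r}; expected one of {', '.join(MODEL_IDS)}"
        ) from None
    return ModelSpec(*flags)


def all_model_specs() -> list[ModelSpec]:
    return [ModelSpec(*flags) for flags in _ID_TO_FLAGS.values()]


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic rate parameters of one model instance.

    Parameters of processes absent from the paired :class:`ModelSpec` are
    stored as exact zeros rather than omitted, so a single rate-term
    implementation serves all eight model structures (absence of a process is
    equivalent to a zero rate).
    """

    alpha: float  # production rate, #/cell/h
    beta: float  # secretion rate constant, 1/h
    gamma: float  # intracellular degradation rate constant, 1/h
    delta: float  # extracellular degradation rate constant, 1/h
    tau: float = 0.0  # maturation delay, h
    epsilon: float = 0.0  # internalization rate constant, 1/h
    kappa: float = 0.0  # production decay rate constant, 1/h

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self.__dataclass_fields__}

    def restricted_to(self, spec: ModelSpec) -> "ParameterSet":
        """Zero out parameters of processes absent from ``spec``."""
        return replace(
            self,
            tau=self.tau if spec.has_delay else 0.0,
            epsilon=self.epsilon if spec.has_internalization else 0.0,
            kappa=self.kappa if spec.has_production_decay else 0.0,
        )

    def validate_for(self, spec: ModelSpec) -> None:
        if not spec.has_delay and self.tau != 0.0:
            raise ValueError("tau must be 0 for models without maturation delay")
        if not spec.has_internalization and self.epsilon != 0.0:
            raise ValueError("epsilon must be 0 for models without internalization")
        if not spec.has_production_decay and self.kappa != 0.0:
            raise ValueError("kappa must be 0 for models without production decay")

    def scaled(self, **factors: float) -> "ParameterSet":
        return replace(
            self, **{k: getattr(self, k) * v for k, v in factors.items()}
        )


@dataclass(frozen=True)
class SystemState:
    """Instantaneous amounts of intracellular and extracellular sFLT1."""

    I: float  # #/cell
    X: float  # #/cell
    t: float = 0.0  # h

    def __post_init__(self) -> None:
        if self.I < 0 or self.X < 0:
            raise ValueError("sFLT1 amounts must be non-negative")


@dataclass(frozen=True)
class CompoundConstants:
    """Ensemble invariants c1 = alpha*beta and c2 = beta+gamma.

    Multistart fits of the delayed model to time-course data leave alpha, beta
    and gamma individually unconstrained but pin these two combinations (plus
    delta and tau), leaving a single residual degree of freedom.
    """

    c1: float  # #/cell/h^2
    c2: float  # 1/h


@dataclass(frozen=True)
class SteadyStateSummary:
    """Constitutive steady states and half-times of both species."""

    I_SS: float  # #/cell
    X_SS: float  # #/cell
    T50_I: float  # h
    T50_X: float  # h


def rate_terms(
    state: SystemState,
    delayed_I: float,
    params: ParameterSet,
    spec: ModelSpec,
    phase: Phase | str,
    t_since_chase: float | None = None,
) -> tuple[float, float]:
    """Instantaneous (dI/dt, dX/dt) for any candidate model.

    ``delayed_I`` is I evaluated at ``t - tau`` for delayed models and at ``t``
    otherwise.  Production is ``alpha`` during pre-simulation, pulse and
    constitutive phases.  During the chase it is ``alpha * exp(-kappa *
    t_since_chase)`` for models with production decay and 0 otherwise, with
    the decay clock starting at the media change (chase start).
    Internalization moves ``epsilon * X`` from the extracellular to the
    intracellular pool when present.
    """
    phase = Phase(phase)
    if delayed_I < 0:
        raise ValueError("delayed_I must be >= 0")
    if phase is Phase.CHASE:
        if t_since_chase is None or t_since_chase < 0:
            raise ValueError("t_since_chase must be provided and >= 0 in the chase phase")
        if spec.has_production_decay:
            production = params.alpha * math.exp(-params.kappa * t_since_chase)
        else:
            production = 0.0
    else:
        production = params.alpha

    internalized = params.epsilon * state.X if spec.has_internalization else 0.0
    dI = production - params.beta * delayed_I - params.gamma * delayed_I + internalized
    dX = params.beta * delayed_I - params.delta * state.X - internalized
    return dI, dX


def steady_state(params: ParameterSet) -> SteadyStateSummary:
    """Closed-form constitutive steady states.

    I_SS = alpha / (beta + gamma), X_SS = (beta / delta) * I_SS, and the
    characteristic half-times T50_I = ln2 / (beta + gamma) and
    T50_X = ln2 / delta.  Valid for models without internalization (the
    delayed model shares these values because I(t - tau) = I(t) at steady
    state).
    """
    c2 = params.beta + params.gamma
    if c2 <= 0:
        raise DegenerateParameterError("beta + gamma must be > 0 for a steady state")
    if params.delta <= 0:
        raise DegenerateParameterError("delta must be > 0 for a steady state")
    i_ss = params.alpha / c2
    x_ss = params.beta / params.delta * i_ss
    return SteadyStateSummary(
        I_SS=i_ss, X_SS=x_ss, T50_I=LN2 / c2, T50_X=LN2 / params.delta
    )


def compound_constants(params: ParameterSet) -> CompoundConstants:
    return CompoundConstants(c1=params.alpha * params.beta, c2=params.beta + params.gamma)


def params_from_beta(
    beta: float,
    constants: CompoundConstants,
    delta: float,
    tau: float = 0.0,
) -> ParameterSet:
    """Construct a parameter set on the constrained manifold from a chosen beta.

    Given the ensemble constraints (c1, c2) plus delta and tau, choosing beta
    in (0, c2] determines alpha = c1/beta and gamma = c2 - beta.  beta = c2
    gives gamma = 0 (no intracellular degradation).
    """
    if beta <= 0 or beta > constants.c2:
        raise ValueError(
            f"beta must satisfy 0 < beta <= c2 = {constants.c2:g}, got {beta:g}"
        )
    return ParameterSet(
        alpha=constants.c1 / beta,
        beta=beta,
        gamma=constants.c2 - beta,
        delta=delta,
        tau=tau,
    )


def theoretical_bounds(constants: CompoundConstants) -> dict[str, float]:
    """Bounds implied by the (c1, c2) constraints on the one-parameter family.

    As beta ranges over (0, c2]: I_SS = c1 / (beta * c2) is minimized at
    beta = c2 giving min I_SS = c1 / c2**2; alpha = c1 / beta is minimized
    there too (min alpha = c1 / c2); and both beta and gamma are capped at c2.
    """
    if constants.c1 <= 0 or constants.c2 <= 0:
        raise ValueError("c1 and c2 must be > 0")
    return {
        "min_I_SS": constants.c1 / constants.c2**2,
        "min_alpha": constants.c1 / constants.c2,
        "max_beta": constants.c2,
        "max_gamma": constants.c2,
    }


# --------------------------------------------------------------------------
# Serialization


def load_parameters(path: str | Path) -> tuple[ParameterSet, ModelSpec]:
    """Read a flat key-value YAML/JSON parameter file (with ``model_id``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of parameter names to values")
    spec = model_from_id(str(raw.pop("model_id", "M1")))
    known = set(ParameterSet.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    params = ParameterSet(**{k: float(v) for k, v in raw.items()})
    params.validate_for(spec)
    return params, spec


def save_parameters(
    params: ParameterSet, spec: ModelSpec, path: str | Path
) -> None:
    payload: dict[str, object] = {"model_id": spec.model_id}
    payload.update(params.as_dict())
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def median_parameters() -> tuple[ParameterSet, ModelSpec]:
    """Reference parameter set: component-wise medians of the accepted fits
    of the delayed model (shipped with the package)."""
    ref = resources.files("sflt1kin.data").joinpath("median_params.yaml")
    with resources.as_file(ref) as path:
        return load_parameters(path)
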