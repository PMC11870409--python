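"""Reading, validation and preprocessing of experimental-style datasets.

A dataset is a tidy CSV (columns ``time_h, species, value, replicate,
excluded``) plus a YAML sidecar holding the metadata that the numbers alone
cannot carry: experiment name, scenario, measurement units, normalization
anchors (for relative units, e.g. quantitative Western blots) and the
cell-density / molar-mass constants needed to convert simulated #/cell into
assay concentrations (for absolute units, e.g. ELISA of conditioned media).

Preprocessing mirrors how time-course data are prepared for optimization:
points flagged as excluded are dropped and replicate measurements are
collapsed to their per-time-point mean so every dataset weighs in with one
value per (species, time).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.constants import Avogadro

from .simulate import Trajectory

__all__ = [
    "UnitConversion",
    "ExperimentalDataset",
    "DatasetError",
    "load_dataset",
    "save_dataset",
    "preprocess",
    "predict_in_dataset_units",
]

OBS_COLUMNS = ["time_h", "species", "value", "replicate", "excluded"]
SPECIES = ("I", "X")
UNIT_KINDS = ("absolute_concentration", "relative")
SCENARIOS = ("constitutive", "pulse_chase")


class DatasetError(ValueError):
    """Schema or content violation in a dataset file."""


@dataclass(frozen=True)
class UnitConversion:
    """Constants converting #/cell to an absolute assay concentration (ng/mL)."""

    cells_per_ml: float = 1.0e5
    molar_mass_g_per_mol: float = 1.1e5  # sFLT1 glycoprotein, ~110 kDa

    @property
    def ng_per_ml_per_molecule_per_cell(self) -> float:
        return self.cells_per_ml * self.molar_mass_g_per_mol / Avogadro * 1e9


@dataclass(frozen=True)
class ExperimentalDataset:
    """Observed sFLT1 values with species, units and preprocessing metadata."""

    name: str
    scenario: str
    observations: pd.DataFrame  # OBS_COLUMNS
    units: str
    anchor_time_X: float | None = None
    anchor_time_I: float | None = None
    conversion: UnitConversion | None = None
    free_scale: bool = False  # fit a per-dataset scale factor (absolute units)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise DatasetError(f"unknown scenario {self.scenario!r}")
        if self.units not in UNIT_KINDS:
            raise DatasetError(f"unknown units {self.units!r}")
        if self.units == "relative":
            species = set(self.observations["species"])
            if "X" in species and self.anchor_time_X is None:
                raise DatasetError("relative-unit dataset with X requires anchor_time_X")
            if "I" in species and self.anchor_time_I is None:
                raise DatasetError("relative-unit dataset with I requires anchor_time_I")
        if self.units == "absolute_concentration" and self.conversion is None:
            object.__setattr__(self, "conversion", UnitConversion())

    @property
    def species_present(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.observations["species"])))

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    def included(self) -> pd.DataFrame:
        return self.observations.loc[~self.observations["excluded"]]


def _validate_observations(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{source}: missing columns {missing}")
    if df.empty:
        raise DatasetError(f"{source}: dataset contains no observations")
    df = df[OBS_COLUMNS].copy()
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header line is 1
        if row["species"] not in SPECIES:
            errors.append(f"line {line}: unknown species {row['species']!r}")
            continue
        try:
            t, v = float(row["time_h"]), float(row["value"])
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric time or value")
            continue
        if not np.isfinite(t) or t < 0:
            errors.append(f"line {line}: time must be finite and >= 0")
        if not np.isfinite(v) or v < 0:
            errors.append(f"line {line}: value must be finite and >= 0")
    if errors:
        raise DatasetError(f"{source}: " + "; ".join(errors))
    df["time_h"] = df["time_h"].astype(float)
    df["value"] = df["value"].astype(float)
    df["excluded"] = df["excluded"].astype(bool)
    return df


def load_dataset(path: str | Path, meta_path: str | Path | None = None) -> ExperimentalDataset:
    """Load a dataset CSV and its YAML metadata sidecar (``<stem>.meta.yaml``)."""
    path = Path(path)
    if meta_path is None:
        meta_path = path.parent / (path.stem + ".meta.yaml")
    meta_path = Path(meta_path)
    if not path.exists():
        raise DatasetError(f"dataset file not found: {path}")
    if not meta_path.exists():
        raise DatasetError(f"metadata sidecar not found: {meta_path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DatasetError(f"{path}: empty dataset file") from None
    df = _validate_observations(df, str(path))
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or {}
    conv = meta.get("conversion")
    return ExperimentalDataset(
        name=str(meta.get("name", path.stem)),
        scenario=str(meta.get("scenario", "constitutive")),
        observations=df,
        units=str(meta.get("units", "relative")),
        anchor_time_X=meta.get("anchor_time_X"),
        anchor_time_I=meta.get("anchor_time_I"),
        conversion=UnitConversion(**conv) if conv else None,
        free_scale=bool(meta.get("free_scale", False)),
    )


def save_dataset(
    dataset: ExperimentalDataset, path: str | Path, meta_path: str | Path | None = None
) -> None:
    path = Path(path)
    if meta_path is None:
        meta_path = path.parent / (path.stem + ".meta.yaml")
    dataset.observations.to_csv(path, index=False)
    meta: dict[str, object] = {
        "name": dataset.name,
        "scenario": dataset.scenario,
        "units": dataset.units,
    }
    if dataset.anchor_time_X is not None:
        meta["anchor_time_X"] = float(dataset.anchor_time_X)
    if dataset.anchor_time_I is not None:
        meta["anchor_time_I"] = float(dataset.anchor_time_I)
    if dataset.conversion is not None:
        meta["conversion"] = {
            "cells_per_ml": dataset.conversion.cells_per_ml,
            "molar_mass_g_per_mol": dataset.conversion.molar_mass_g_per_mol,
        }
    if dataset.free_scale:
        meta["free_scale"] = True
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def preprocess(dataset: ExperimentalDataset) -> ExperimentalDataset:
    """Drop excluded points and collapse replicates to per-time-point means.

    Idempotent; output rows are deterministically ordered by (species, time).
    """
    df = dataset.included()
    collapsed = (
        df.groupby(["species", "time_h"], as_index=False)["value"]
        .mean()
        .sort_values(["species", "time_h"], kind="mergesort")
        .reset_index(drop=True)
    )
    collapsed["replicate"] = 0
    collapsed["excluded"] = False
    return replace(dataset, observations=collapsed[OBS_COLUMNS])


def predict_in_dataset_units(
    traj: Trajectory, dataset: ExperimentalDataset
) -> pd.DataFrame:
    """Evaluate a simulated trajectory at the dataset's (time, species) points,
    converted to the dataset's measurement units.

    Relative datasets: each species is normalized by the simulated value at
    that dataset's anchor time.  Absolute datasets: #/cell is converted to
    ng/mL using the dataset's cell density and molar mass.  Values between
    1-minute reports are obtained by linear interpolation.
    """
    obs = dataset.included()
    t_min, t_max = float(traj.times[0]), float(traj.times[-1])
    if obs["time_h"].min() < t_min - 1e-9 or obs["time_h"].max() > t_max + 1e-9:
        raise ValueError(
            f"trajectory [{t_min}, {t_max}] h does not cover dataset "
            f"{dataset.name!r} time points"
        )
    rows = []
    for species, grp in obs.groupby("species", sort=True):
        values = np.asarray(traj.value_at(species, grp["time_h"].to_numpy()), dtype=float)
        if dataset.units == "relative":
            anchor = dataset.anchor_time_X if species == "X" else dataset.anchor_time_I
            if anchor is None or anchor < t_min - 1e-9 or anchor > t_max + 1e-9:
                raise ValueError(f"anchor time {anchor} outside trajectory for {species}")
            ref = float(traj.value_at(species, anchor))
            if ref <= 0:
                raise ValueError(f"zero anchor value for species {species}")
            values = values / ref
            units = "relative"
        else:
            values = values * dataset.conversion.ng_per_ml_per_molecule_per_cell
            units = "ng/mL"
        rows.append(
            pd.DataFrame(
                {
                    "time_h": grp["time_h"].to_numpy(),
                    "species": species,
                    "predicted": values,
                    "units": units,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
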