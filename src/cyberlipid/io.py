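"""Tidy CSV / YAML / JSON interchange for the pipeline stages.

The measurement schema is a long-format CSV with header
``condition,time_min,species,replicate,value`` — one row per replicate
observation — so new conditions, species or replicates extend the file
without schema changes.  Input profiles use the same layout without the
replicate column.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .estimation import ExperimentDataset, FitConfig, FitResult
from .network import KineticParameters
from .simulation import InputProfiles, Trajectory

__all__ = [
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "read_profiles",
    "write_profiles",
    "write_trajectories",
    "write_results_json",
    "read_params_json",
]

DATASET_COLUMNS = ["condition", "time_min", "species", "replicate", "value"]
PROFILE_COLUMNS = ["condition", "time_min", "species", "value"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def read_timeseries(path) -> dict[str, ExperimentDataset]:
    """Read replicate measurements; returns one dataset per condition.

    Negative values and duplicated (condition, species, time, replicate)
    keys are reported with their row number (1-based, excluding header).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, DATASET_COLUMNS, path)
    neg = df.index[df["value"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative value at row {neg[0] + 2}")
    key = ["condition", "species", "time_min", "replicate"]
    dup = df.index[df.duplicated(subset=key)]
    if len(dup):
        raise ValueError(f"{path}: duplicated measurement at row {dup[0] + 2}")
    out = {}
    for cond in df["condition"].unique():
        sub = df[df["condition"] == cond]
        reps = sorted(int(r) for r in sub["replicate"].unique())
        if reps != list(range(1, len(reps) + 1)):
            raise ValueError(
                f"{path}: replicate indices for condition {cond!r} must be "
                f"contiguous from 1, got {reps}"
            )
        out[str(cond)] = ExperimentDataset.from_frame(sub)
    return out


def write_timeseries(datasets: Mapping[str, ExperimentDataset], path) -> None:
    frames = [ds.to_frame() for ds in datasets.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_profiles(path) -> dict[str, InputProfiles]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PROFILE_COLUMNS, path)
    if (df["value"] < 0).any():
        row = df.index[df["value"] < 0][0]
        raise ValueError(f"{path}: negative value at row {row + 2}")
    return {
        str(cond): InputProfiles.from_frame(df, condition=cond)
        for cond in df["condition"].unique()
    }


def write_profiles(profiles: Mapping[str, InputProfiles], path) -> None:
    frames = [p.to_frame() for p in profiles.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def write_trajectories(trajectories: Mapping[str, Trajectory], path) -> None:
    frames = [t.to_frame() for t in trajectories.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """Configuration for the command-line pipeline."""

    variant: str = "EPA"
    conditions: tuple[str, ...] = ("ctrl", "EPA")
    data_path: str = "data.csv"
    profiles_path: str = "profiles.csv"
    params_path: str = "fit.json"
    optimizer: dict[str, Any] = field(default_factory=dict)
    solver: dict[str, float] = field(
        default_factory=lambda: {"rtol": 1e-6, "atol": 1e-9}
    )
    alpha: float = 0.05
    synthetic: dict[str, Any] = field(default_factory=dict)

    def fit_config(self) -> FitConfig:
        opts = dict(self.optimizer)
        opts.setdefault("conditions", tuple(self.conditions))
        opts["conditions"] = tuple(opts["conditions"])
        return FitConfig(**opts)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["conditions"] = list(data["conditions"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_results_json(
    path,
    fit_result: FitResult | None = None,
    extra: Mapping[str, Any] | None = None,
    config: RunConfig | None = None,
) -> None:
    """Serialize fit results (and any extra tables) to JSON."""
    payload: dict[str, Any] = {}
    if fit_result is not None:
        payload.update(fit_result.to_json_dict())
    if extra:
        payload.update(extra)
    if config is not None:
        payload["config_hash"] = config.digest()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_params_json(path) -> KineticParameters:
    with open(path) as fh:
        payload = json.load(fh)
    return KineticParameters(payload["parameters"])
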