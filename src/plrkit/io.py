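"""File formats: trace CSV, stimulus sidecar YAML/JSON, parameter files."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .model import PLRParameters, PupilTrace, StimulusSpec

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_stimulus",
    "write_stimulus",
    "read_params",
    "write_params",
]

TRACE_COLUMNS = ("time_s", "radius_mm")


def read_trace_csv(path) -> PupilTrace:
    """Read a two-column ``time_s, radius_mm`` CSV (header required)."""
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trace columns {sorted(missing)}")
    return PupilTrace(df["time_s"].to_numpy(), df["radius_mm"].to_numpy())


def write_trace_csv(trace: PupilTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "radius_mm": trace.radii}).to_csv(
        path, index=False
    )


def read_stimulus(path) -> StimulusSpec:
    """Read a stimulus sidecar (YAML or JSON) holding ``t_s`` and ``t_d``."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return StimulusSpec(t_s=float(data["t_s"]), t_d=float(data["t_d"]))


def write_stimulus(stim: StimulusSpec, path, **metadata) -> None:
    """Write a stimulus sidecar; extra labels (colour, intensity) pass through."""
    path = Path(path)
    data = {"t_s": stim.t_s, "t_d": stim.t_d, **metadata}
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh)


def read_params(path) -> PLRParameters:
    """Read a parameter vector from JSON or single-column CSV keyed by name."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            return PLRParameters.from_dict(json.load(fh))
    df = pd.read_csv(path, index_col=0)
    return PLRParameters.from_dict(df.iloc[:, 0].to_dict())


def write_params(params: PLRParameters, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump(params.as_dict(), fh, indent=2)
    else:
        pd.Series(params.as_dict(), name="value").rename_axis("parameter").to_csv(path)
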