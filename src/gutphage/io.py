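"""Readers and writers for the package's plain-text file dialects.

All files are CSV with a header row; provenance (generating parameters,
seeds, solver settings) travels in ``#``-prefixed comment lines before the
header.  Floats are emitted with 9 significant digits and scientific
notation is accepted on read.

Dialects
--------
* parameters: flat ``key = value`` text, keys d,r,k,x,l,y,a,g;
* trajectory: ``time_h,S,L,SL,Q,V``;
* observations: ``mouse_id,time_h,compartment,count_per_g``;
* assay: ``time_h,value`` (series kinds) or ``n_centres,n_plated``;
* sweep: ``parameter,value,initial_ratio,final_ratio``.
"""

from __future__ import annotations

import io as _io
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import AssayDataset
from .model import PARAM_NAMES, ModelParameters, Trajectory
from .observations import FecalObservationSet
from .sensitivity import SweepResult

__all__ = [
    "default_parameters_path",
    "read_params",
    "write_params",
    "read_key_value",
    "write_trajectory",
    "read_trajectory",
    "write_observations",
    "read_observations",
    "write_assay",
    "read_assay",
    "write_sweep",
    "read_sweep",
]

FLOAT_FMT = "%.9g"


def default_parameters_path() -> Path:
    """Path of the packaged default (calibrated gut) parameter file."""
    return Path(str(resources.files("gutphage").joinpath("data/default_params.txt")))


def read_key_value(path) -> dict[str, str]:
    """Parse a flat ``key = value`` file; raises with the offending line number."""
    result: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key or not value:
            raise ValueError(f"{path}:{lineno}: empty key or value in {raw!r}")
        result[key] = value
    return result


def read_params(path) -> ModelParameters:
    """Read a parameter file (keys d,r,k,x,l,y,a,g)."""
    raw = read_key_value(path)
    unknown = set(raw) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}; expected {PARAM_NAMES}")
    missing = set(PARAM_NAMES) - set(raw)
    if missing:
        raise ValueError(f"{path}: missing parameter keys {sorted(missing)}")
    try:
        values = {key: float(raw[key]) for key in PARAM_NAMES}
    except ValueError as err:
        raise ValueError(f"{path}: non-numeric parameter value ({err})") from err
    return ModelParameters(**values)


def write_params(params: ModelParameters, path, header: str | None = None) -> None:
    lines = []
    if header:
        lines.extend(f"# {line}" for line in header.splitlines())
    lines.extend(f"{name} = {FLOAT_FMT % getattr(params, name)}" for name in PARAM_NAMES)
    Path(path).write_text("\n".join(lines) + "\n")


def _write_csv(frame: pd.DataFrame, path, comments: list[str]) -> None:
    buf = _io.StringIO()
    for comment in comments:
        buf.write(f"# {comment}\n")
    frame.to_csv(buf, index=False, float_format=FLOAT_FMT)
    Path(path).write_text(buf.getvalue())


def _read_csv(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a CSV, returning the table and its '#' provenance block as a dict."""
    meta: dict[str, str] = {}
    with open(path) as handle:
        text = handle.read()
    lines = text.splitlines()
    start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        start += 1
        body = line.lstrip("#").strip()
        if "=" in body:
            key, value = (part.strip() for part in body.split("=", 1))
            meta[key] = value
    frame = pd.read_csv(_io.StringIO("\n".join(lines[start:])))
    return frame, meta


def write_trajectory(traj: Trajectory, path) -> None:
    comments = [f"param_{name} = {FLOAT_FMT % getattr(traj.params, name)}" for name in PARAM_NAMES]
    comments += [f"solver_{key} = {value}" for key, value in traj.meta.items()]
    _write_csv(traj.to_frame(), path, comments)


def read_trajectory(path) -> tuple[pd.DataFrame, dict[str, str]]:
    frame, meta = _read_csv(path)
    expected = ["time_h", "S", "L", "SL", "Q", "V"]
    if list(frame.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    return frame, meta


def write_observations(obs: FecalObservationSet, path) -> None:
    comments = [
        f"scenario = {obs.scenario}",
        f"detection_limit = {FLOAT_FMT % obs.detection_limit}",
    ]
    if obs.seed is not None:
        comments.append(f"seed = {obs.seed}")
    for key, value in obs.noise.items():
        comments.append(f"{key} = {FLOAT_FMT % value}")
    if isinstance(obs.params, ModelParameters):
        comments += [f"param_{name} = {FLOAT_FMT % getattr(obs.params, name)}" for name in PARAM_NAMES]
    frame = obs.data[["mouse_id", "time_h", "compartment", "count_per_g"]]
    _write_csv(frame, path, comments)


def read_observations(path) -> FecalObservationSet:
    frame, meta = _read_csv(path)
    expected = ["mouse_id", "time_h", "compartment", "count_per_g"]
    if list(frame.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    frame = frame.astype({"time_h": float, "count_per_g": float})
    params = None
    if all(f"param_{name}" in meta for name in PARAM_NAMES):
        params = ModelParameters(**{name: float(meta[f"param_{name}"]) for name in PARAM_NAMES})
    noise = {key: float(meta[key]) for key in ("noise_cv", "initial_cv") if key in meta}
    return FecalObservationSet(
        data=frame,
        scenario=meta.get("scenario", "unknown"),
        detection_limit=float(meta.get("detection_limit", 1e2)),
        params=params,
        noise=noise,
        seed=int(meta["seed"]) if "seed" in meta else None,
    )


def write_assay(data: AssayDataset, path) -> None:
    comments = [f"kind = {data.kind}"]
    if data.kind == "infective_centre":
        frame = pd.DataFrame({"n_centres": [data.n_centres], "n_plated": [data.n_plated]})
    else:
        if data.B is not None:
            comments.append(f"B = {FLOAT_FMT % data.B}")
        frame = pd.DataFrame({"time_h": data.times, "value": data.values})
    _write_csv(frame, path, comments)


def read_assay(path) -> AssayDataset:
    frame, meta = _read_csv(path)
    kind = meta.get("kind")
    if kind is None:
        raise ValueError(f"{path}: missing '# kind = ...' header line")
    if kind == "infective_centre":
        row = frame.iloc[0]
        return AssayDataset(kind=kind, n_centres=int(row["n_centres"]), n_plated=int(row["n_plated"]))
    return AssayDataset(
        kind=kind,
        times=frame["time_h"].to_numpy(dtype=float),
        values=frame["value"].to_numpy(dtype=float),
        B=float(meta["B"]) if "B" in meta else None,
    )


def write_sweep(sweep: SweepResult, path) -> None:
    _write_csv(sweep.to_frame(), path, [f"horizon_h = {FLOAT_FMT % sweep.horizon}"])


def read_sweep(path) -> pd.DataFrame:
    frame, _ = _read_csv(path)
    expected = ["parameter", "value", "initial_ratio", "final_ratio"]
    if list(frame.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    return frame
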