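"""Trace CSV readers/writers and run-configuration loading.

Trace files are plain CSV with header ``time_s,temp_c[,label]``; comment
lines starting with ``#`` (used for provenance headers) are ignored.
Run configurations are YAML or JSON in clinical units::

    volume_ml: 38.3
    t0_c: 22.0
    t_in_c: 22.0
    flow_ml_min: 20.0
    beta_w_per_c: 1.36
    laser:
      - {on_s: 20.0, off_s: 80.0, power_w: 40.0}
    fluid: {k: 0.606, rho: 1000.0, c: 4180.0}
    dose: {threshold_min: 120.0, tail_taus: 10.0}

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np
import yaml

from . import __version__
from .core import FluidProperties, LaserSchedule, SystemConfig, TemperatureTrace
from .dose import DOSE_THRESHOLD_MIN

__all__ = [
    "TraceFormatError",
    "ConfigError",
    "RunConfig",
    "read_trace_csv",
    "write_trace_csv",
    "load_run_config",
    "read_manifest_traces",
]


class TraceFormatError(ValueError):
    """A trace CSV failed validation; the message names the offending line."""


class ConfigError(ValueError):
    """A run-configuration file failed validation."""


@dataclass(frozen=True)
class DosePolicy:
    threshold_min: float = DOSE_THRESHOLD_MIN
    tail_taus: float = 10.0
    horizon_s: float | None = None


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved run: system, schedule and dose policy."""

    system: SystemConfig
    schedule: LaserSchedule
    dose: DosePolicy = field(default_factory=DosePolicy)


def read_trace_csv(path: str | Path) -> TemperatureTrace:
    """Read and validate a ``time_s,temp_c[,label]`` CSV trace.

    Raises :class:`TraceFormatError` naming the first offending line for
    malformed headers, non-numeric cells or non-increasing times.
    """
    path = Path(path)
    times: list[float] = []
    temps: list[float] = []
    label = path.stem
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = None
        header_line = 0
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            if header is None:
                header = [c.strip().lower() for c in row]
                header_line = lineno
                if header[:2] != ["time_s", "temp_c"]:
                    raise TraceFormatError(
                        f"{path}:{lineno}: expected header 'time_s,temp_c[,label]', got {','.join(row)!r}"
                    )
                continue
            if len(row) < 2:
                raise TraceFormatError(f"{path}:{lineno}: expected at least 2 columns, got {len(row)}")
            try:
                t = float(row[0])
                T = float(row[1])
            except ValueError as exc:
                raise TraceFormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if times and t <= times[-1]:
                raise TraceFormatError(
                    f"{path}:{lineno}: time {t} is not strictly greater than previous {times[-1]}"
                )
            times.append(t)
            temps.append(T)
            if len(row) > 2 and row[2].strip():
                label = row[2].strip()
    if header is None:
        raise TraceFormatError(f"{path}: empty file (no header)")
    if len(times) < 2:
        raise TraceFormatError(f"{path}: need at least 2 data rows, found {len(times)}")
    try:
        return TemperatureTrace(times=np.asarray(times), temps=np.asarray(temps), label=label)
    except ValueError as exc:
        raise TraceFormatError(f"{path}: {exc}") from None


def _provenance(meta: dict | None) -> str:
    parts = [f"lithotherm v{__version__}"]
    if meta:
        parts += [f"{k}={v}" for k, v in meta.items()]
    return "# " + " | ".join(parts)


def write_trace_csv(
    trace: TemperatureTrace,
    path_or_file: str | Path | IO[str],
    meta: dict | None = None,
) -> None:
    """Write a trace as CSV with a ``#`` provenance header, 6-decimal fixed point."""

    def _write(fh: IO[str]) -> None:
        fh.write(_provenance(meta) + "\n")
        fh.write("time_s,temp_c,label\n")
        for t, T in zip(trace.times, trace.temps):
            fh.write(f"{t:.6f},{T:.6f},{trace.label}\n")

    if hasattr(path_or_file, "write"):
        _write(path_or_file)  # type: ignore[arg-type]
    else:
        with Path(path_or_file).open("w", newline="") as fh:
            _write(fh)


def read_manifest_traces(manifest_path: str | Path) -> dict[str, TemperatureTrace]:
    """Load every trace listed in a synthetic-grid ``manifest.csv``.

    Trace files are resolved relative to the manifest's directory.
    """
    import pandas as pd

    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, comment="#")
    if "filename" not in manifest.columns:
        raise ConfigError(f"{manifest_path}: manifest lacks a 'filename' column")
    return {
        name: read_trace_csv(manifest_path.parent / name) for name in manifest["filename"]
    }


_TOP_KEYS = {
    "name",
    "volume_ml",
    "t0_c",
    "t_in_c",
    "flow_ml_min",
    "beta_w_per_c",
    "laser",
    "fluid",
    "dose",
    "firing_s",
}
_FLUID_KEYS = {"k", "rho", "c"}
_LASER_KEYS = {"on_s", "off_s", "power_w"}
_DOSE_KEYS = {"threshold_min", "tail_taus", "horizon_s"}


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration, validating units and keys."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    _check_keys(raw, _TOP_KEYS, str(path))
    for req in ("volume_ml", "t0_c", "beta_w_per_c"):
        if req not in raw:
            raise ConfigError(f"{path}: missing required key {req!r}")

    fluid_raw = raw.get("fluid", {})
    _check_keys(fluid_raw, _FLUID_KEYS, f"{path}:fluid")
    fluid = FluidProperties(**{**{"k": 0.606, "rho": 1000.0, "c": 4180.0}, **fluid_raw})

    try:
        system = SystemConfig.from_clinical(
            volume_ml=float(raw["volume_ml"]),
            t0_c=float(raw["t0_c"]),
            beta_w_per_c=float(raw["beta_w_per_c"]),
            flow_ml_min=float(raw.get("flow_ml_min", 0.0)),
            t_in_c=None if raw.get("t_in_c") is None else float(raw["t_in_c"]),
            fluid=fluid,
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None

    intervals = []
    for i, item in enumerate(raw.get("laser", [])):
        _check_keys(item, _LASER_KEYS, f"{path}:laser[{i}]")
        try:
            intervals.append((float(item["on_s"]), float(item["off_s"]), float(item["power_w"])))
        except KeyError as exc:
            raise ConfigError(f"{path}:laser[{i}]: missing key {exc}") from None
    try:
        schedule = LaserSchedule(intervals=tuple(intervals))
    except ValueError as exc:
        raise ConfigError(f"{path}: invalid laser schedule: {exc}") from None

    dose_raw = raw.get("dose", {})
    _check_keys(dose_raw, _DOSE_KEYS, f"{path}:dose")
    dose = DosePolicy(
        threshold_min=float(dose_raw.get("threshold_min", DOSE_THRESHOLD_MIN)),
        tail_taus=float(dose_raw.get("tail_taus", 10.0)),
        horizon_s=None if dose_raw.get("horizon_s") is None else float(dose_raw["horizon_s"]),
    )
    return RunConfig(system=system, schedule=schedule, dose=dose)
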