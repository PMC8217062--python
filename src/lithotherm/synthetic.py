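"""Synthetic thermocouple traces emulating the benchtop experiment grid.

Real acquisitions pair two laser powers (10 and 40 W) with three irrigation
rates (0, 20, 40 mL/min), five repeat runs per cell, recorded at 0.1 s for
20 s of irrigation-only lead-in, 60 s of firing and 20 s of cool-down.
The generator samples the analytic model solution on that grid and adds
i.i.d. Gaussian measurement noise (default sigma = 0.2 degC, a plausible
T-type thermocouple precision).  Every trace is deterministic in the seed;
per-run sub-seeds are spawned from (seed, cell index, run index) so any
single run can be regenerated without the rest.

What this emulates — and what it does not: additive sensor noise on a
perfectly lumped temperature.  Real traces additionally carry flow-rate
drift, probe-placement effects and wall-property variation, none of which
are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LaserSchedule, SystemConfig, TemperatureTrace, temperature_trace
from .presets import COOL_DOWN_S, FIRING_S, LEAD_IN_S, default_schedule, load_preset, _to_config

__all__ = ["ExperimentGridSpec", "generate_run", "generate_grid", "DEFAULT_NOISE_SIGMA"]

#: default additive measurement-noise standard deviation, degC
DEFAULT_NOISE_SIGMA = 0.2


@dataclass(frozen=True)
class ExperimentGridSpec:
    """The experiment grid to emulate: powers x flows x repeat runs."""

    preset: str = "setB"
    powers_w: tuple[float, ...] = (10.0, 40.0)
    flows_ml_min: tuple[float, ...] = (0.0, 20.0, 40.0)
    runs_per_cell: int = 5
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    sample_dt: float = 0.1
    seed: int = 0
    lead_in_s: float = LEAD_IN_S
    firing_s: float = FIRING_S
    cool_down_s: float = COOL_DOWN_S

    def __post_init__(self) -> None:
        if self.runs_per_cell < 1:
            raise ValueError("runs_per_cell must be >= 1")
        if not self.sample_dt > 0:
            raise ValueError("sample_dt must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def generate_run(
    cfg: SystemConfig,
    schedule: LaserSchedule,
    beta_true: float,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    sample_dt: float = 0.1,
    seed: int | np.random.SeedSequence = 0,
    t_end: float | None = None,
    label: str = "synthetic",
) -> TemperatureTrace:
    """One noisy synthetic acquisition.

    The analytic model (with ``cfg.beta`` replaced by ``beta_true``) is
    sampled every ``sample_dt`` seconds from 0 to ``t_end`` (default: last
    laser-off plus a 20 s cool-down) and i.i.d. Gaussian noise of standard
    deviation ``noise_sigma`` is added.  ``noise_sigma = 0`` reproduces the
    model exactly; a fixed seed reproduces the trace bit for bit.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if t_end is None:
        t_end = (schedule.t_last_off if schedule.intervals else 0.0) + COOL_DOWN_S
    grid = np.arange(0.0, t_end + sample_dt / 2.0, sample_dt)
    clean = temperature_trace(cfg.replace(beta=beta_true), schedule, grid, label=label)
    rng = np.random.default_rng(seed)
    noisy = clean.temps + rng.normal(0.0, noise_sigma, size=clean.temps.shape) if noise_sigma > 0 else clean.temps
    return TemperatureTrace(times=clean.times, temps=noisy, label=label)


def generate_grid(
    spec: ExperimentGridSpec,
    beta_true: float | None = None,
) -> tuple[dict[str, TemperatureTrace], pd.DataFrame]:
    """Generate the full grid of synthetic runs plus a manifest.

    Returns ``(traces, manifest)`` where ``traces`` maps a run identifier
    (also the suggested file name) to its trace and the manifest records
    the settings of every run.  ``beta_true`` defaults to the preset's
    fitted value.
    """
    preset = load_preset(spec.preset)
    base_cfg = _to_config(preset)
    if beta_true is None:
        beta_true = preset["beta_w_per_c"]
    root = np.random.SeedSequence(spec.seed)

    traces: dict[str, TemperatureTrace] = {}
    records = []
    cell_idx = 0
    for power in spec.powers_w:
        for flow in spec.flows_ml_min:
            cfg = base_cfg.replace(Q=flow * 1e-6 / 60.0)
            schedule = default_schedule(power, spec.lead_in_s, spec.firing_s)
            for run in range(spec.runs_per_cell):
                sub = np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(cell_idx, run)
                )
                name = f"{preset['name']}_W{power:g}_Q{flow:g}_run{run}.csv"
                traces[name] = generate_run(
                    cfg,
                    schedule,
                    beta_true,
                    noise_sigma=spec.noise_sigma,
                    sample_dt=spec.sample_dt,
                    seed=sub,
                    t_end=spec.lead_in_s + spec.firing_s + spec.cool_down_s,
                    label=name.removesuffix(".csv"),
                )
                records.append(
                    {
                        "filename": name,
                        "preset": preset["name"],
                        "power_w": power,
                        "flow_ml_min": flow,
                        "run": run,
                        "beta_true_w_per_c": beta_true,
                        "noise_sigma_c": spec.noise_sigma,
                        "sample_dt_s": spec.sample_dt,
                        "seed": spec.seed,
                    }
                )
            cell_idx += 1
    return traces, pd.DataFrame(records)
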