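"""Packaged benchtop presets.

Two validated in vitro configurations ship with the package:

* **Set A** — a 5.89 mL test tube (the scale of an isolated renal calyx)
  in a 37 degC bath with 23 degC irrigation; fitted wall heat-loss
  coefficient ``beta = 1.15 W/degC``.
* **Set B** — a 38.3 mL cylinder (typical kidney collecting-system scale)
  with bath and irrigation both at 22 degC; fitted ``beta = 1.36 W/degC``.

Both assume water as the working fluid.  The default acquisition protocol
for either preset is 20 s irrigation-only lead-in, 60 s firing and 20 s
cool-down, sampled at 0.1 s.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .core import FluidProperties, LaserSchedule, SystemConfig

__all__ = [
    "BETA_SET_A",
    "BETA_SET_B",
    "load_preset",
    "set_a",
    "set_b",
    "default_schedule",
    "PRESET_NAMES",
]

BETA_SET_A = 1.15
BETA_SET_B = 1.36

PRESET_NAMES = ("setA", "setB")
_FILES = {"setA": "set_a.yaml", "setB": "set_b.yaml"}

#: default acquisition timing (s): lead-in, firing, cool-down
LEAD_IN_S = 20.0
FIRING_S = 60.0
COOL_DOWN_S = 20.0


def load_preset(name: str) -> dict:
    """Raw preset dictionary (clinical units) for ``setA`` or ``setB``."""
    key = name.replace("_", "").replace("-", "").lower()
    for canonical, fname in _FILES.items():
        if canonical.lower() == key or canonical.lower().removeprefix("set") == key.removeprefix("set"):
            text = resources.files("lithotherm").joinpath("data", fname).read_text()
            return yaml.safe_load(text)
    raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")


def _to_config(d: dict) -> SystemConfig:
    fluid = FluidProperties(**d.get("fluid", {}))
    return SystemConfig.from_clinical(
        volume_ml=d["volume_ml"],
        t0_c=d["t0_c"],
        beta_w_per_c=d["beta_w_per_c"],
        flow_ml_min=d.get("flow_ml_min", 0.0),
        t_in_c=d.get("t_in_c"),
        fluid=fluid,
    )


def set_a(flow_ml_min: float | None = None) -> SystemConfig:
    """Set A configuration, optionally overriding the irrigation rate."""
    d = load_preset("setA")
    if flow_ml_min is not None:
        d["flow_ml_min"] = flow_ml_min
    return _to_config(d)


def set_b(flow_ml_min: float | None = None) -> SystemConfig:
    """Set B configuration, optionally overriding the irrigation rate."""
    d = load_preset("setB")
    if flow_ml_min is not None:
        d["flow_ml_min"] = flow_ml_min
    return _to_config(d)


def default_schedule(power_w: float, lead_in_s: float = LEAD_IN_S, firing_s: float = FIRING_S) -> LaserSchedule:
    """Single-burst schedule: laser on after the lead-in, off ``firing_s`` later."""
    return LaserSchedule.single(lead_in_s, lead_in_s + firing_s, power_w)
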