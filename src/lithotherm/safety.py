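"""Safe firing times and parameter-scan tables.

``safe_firing_time`` finds the longest uninterrupted laser firing time
``tf_safe`` whose temperature history (firing plus cool-down) keeps the t43
thermal dose at or below a threshold (120 equivalent minutes at 43 degC by
convention).  Because the dose is non-decreasing in the firing time the
problem is a bracketed bisection on ``tf -> t43(tf)``.

Three regimes follow from the on-phase steady state ``T*``:

* ``T* <= 37`` — no dose ever accrues; ``tf_safe`` is infinite,
* ``37 < T* < 43`` — dose accrues at most 1 equivalent min per min; finite
  but possibly very long ``tf_safe``,
* ``T* >= 43`` — dose accrues at least 1 equivalent min per min; short
  ``tf_safe``.

The scan helpers build long-format tables of temperature change after a
fixed firing time over two of (flow, power, volume), and of ``tf_safe``
over (irrigation temperature, flow), including the analytic flow values at
which ``T*`` crosses 37 and 43 degC for each irrigation temperature.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    LaserSchedule,
    SystemConfig,
    delta_T_after_firing,
    heat_load,
    ml_min_to_m3_s,
    ml_to_m3,
)
from .dose import DOSE_THRESHOLD_MIN, DoseResult, t43_of_model

__all__ = ["SafeTimeResult", "safe_firing_time", "scan_delta_T", "scan_safe_time"]

REGIME_NO_DOSE = "no-dose"
REGIME_SUB_43 = "sub-43"
REGIME_SUPRA_43 = "supra-43"

#: cap on the bracket search; beyond a day of continuous firing the safe
#: time is reported as effectively infinite
_TF_CAP_S = 86_400.0
_BISECT_TOL_S = 1e-3


@dataclass(frozen=True)
class SafeTimeResult:
    """Solved safe firing time with diagnostics.

    ``tf_safe`` is in seconds (``math.inf`` in the no-dose regime or when
    the dose stays under threshold up to the search cap).  ``dose_at_tf``
    re-evaluates the t43 dose at the returned time; for a finite solution
    it equals the threshold within solver tolerance.  ``dose_truncated``
    flags dose integrals whose cool-down tail had to be cut (asymptote
    above 37 degC), making reported doses lower bounds.
    """

    tf_safe: float
    regime: str
    dose_at_tf: float
    tstar_on: float
    threshold_min: float = DOSE_THRESHOLD_MIN
    dose_truncated: bool = False
    note: str = ""

    @property
    def tf_safe_min(self) -> float:
        """Safe firing time in minutes."""
        return self.tf_safe / 60.0


def _dose_for_tf(cfg: SystemConfig, W: float, tf: float, tail_taus: float) -> DoseResult:
    sched = LaserSchedule.single(0.0, tf, W)
    return t43_of_model(cfg, sched, tail_taus=tail_taus)


def safe_firing_time(
    cfg: SystemConfig,
    W: float,
    threshold_min: float = DOSE_THRESHOLD_MIN,
    tail_taus: float = 10.0,
    tol_s: float = _BISECT_TOL_S,
) -> SafeTimeResult:
    """Longest firing time keeping the t43 dose at or below ``threshold_min``.

    Firing starts at ``t = 0`` from the bath temperature and the dose is
    integrated over firing plus cool-down.  When the on-phase steady state
    is at or below 37 degC no dose ever accrues and ``tf_safe`` is
    infinite.  Otherwise the threshold crossing is bracketed by geometric
    growth and solved by bisection to ``tol_s``.
    """
    if not threshold_min > 0:
        raise ValueError(f"threshold must be > 0 minutes, got {threshold_min!r}")
    if not W > 0:
        raise ValueError(f"laser power must be > 0, got {W!r}")
    tstar, _ = heat_load(cfg, W)

    if tstar <= 37.0:
        return SafeTimeResult(
            tf_safe=math.inf,
            regime=REGIME_NO_DOSE,
            dose_at_tf=0.0,
            tstar_on=tstar,
            threshold_min=threshold_min,
        )
    regime = REGIME_SUB_43 if tstar < 43.0 else REGIME_SUPRA_43

    # bracket: grow hi until the dose exceeds the threshold or hits the cap
    lo, hi = 0.0, 60.0
    truncated_seen = False
    while True:
        d = _dose_for_tf(cfg, W, hi, tail_taus)
        truncated_seen = truncated_seen or d.truncated
        if d.t43 > threshold_min:
            break
        lo = hi
        hi *= 2.0
        if hi > _TF_CAP_S:
            note = "dose stays below threshold up to the 24 h search cap"
            if truncated_seen:
                note += "; dose integrals were truncated (cool-down asymptote above 37 degC)"
            return SafeTimeResult(
                tf_safe=math.inf,
                regime=regime,
                dose_at_tf=d.t43,
                tstar_on=tstar,
                threshold_min=threshold_min,
                dose_truncated=truncated_seen,
                note=note,
            )

    while hi - lo > tol_s:
        mid = 0.5 * (lo + hi)
        d = _dose_for_tf(cfg, W, mid, tail_taus)
        truncated_seen = truncated_seen or d.truncated
        if d.t43 <= threshold_min:
            lo = mid
        else:
            hi = mid
    final = _dose_for_tf(cfg, W, max(lo, tol_s), tail_taus)
    return SafeTimeResult(
        tf_safe=lo,
        regime=regime,
        dose_at_tf=final.t43,
        tstar_on=tstar,
        threshold_min=threshold_min,
        dose_truncated=truncated_seen or final.truncated,
    )


_AXIS_UNITS = {"Q": "flow_ml_min", "W": "power_w", "V": "volume_ml"}


def scan_delta_T(
    cfg: SystemConfig,
    W: float,
    t_f: float = 60.0,
    q_ml_min: np.ndarray | list | None = None,
    w_watts: np.ndarray | list | None = None,
    v_ml: np.ndarray | list | None = None,
) -> pd.DataFrame:
    """Temperature change after ``t_f`` seconds of firing over a 2-D grid.

    Exactly two of ``q_ml_min``, ``w_watts``, ``v_ml`` must be given; the
    remaining quantity is taken from ``cfg`` (or ``W``).  Returns a
    long-format table with the two axis columns (clinical units) and
    ``delta_T_c``.  Negative entries mark conditions where cold irrigation
    outweighs laser heating.
    """
    axes = {"Q": q_ml_min, "W": w_watts, "V": v_ml}
    given = [k for k, v in axes.items() if v is not None]
    if len(given) != 2:
        raise ValueError("exactly two of q_ml_min, w_watts, v_ml must be provided")
    a1, a2 = given
    vals1 = np.asarray(axes[a1], dtype=float)
    vals2 = np.asarray(axes[a2], dtype=float)
    if vals1.size == 0 or vals2.size == 0:
        raise ValueError("grid axes must be non-empty")

    rows = []
    for x1, x2 in itertools.product(vals1, vals2):
        c = cfg
        w = W
        for name, val in ((a1, x1), (a2, x2)):
            if name == "Q":
                c = c.replace(Q=ml_min_to_m3_s(val))
            elif name == "V":
                c = c.replace(V=ml_to_m3(val))
            else:
                w = val
        rows.append(
            {
                _AXIS_UNITS[a1]: x1,
                _AXIS_UNITS[a2]: x2,
                "delta_T_c": delta_T_after_firing(c, w, t_f),
            }
        )
    return pd.DataFrame(rows)


def _q_at_tstar(cfg: SystemConfig, W: float, tin: float, level: float) -> float:
    """Flow (mL/min) at which the on-phase steady state equals ``level`` degC.

    From the flux balance ``W = rho*c*Q*(level - Tin) + beta*(level - T0)``.
    Returns ``nan`` when no non-negative finite flow achieves it.
    """
    rc = cfg.fluid.volumetric_heat_capacity
    num = W - cfg.beta * (level - cfg.T0)
    den = rc * (level - tin)
    if den <= 0:
        return math.nan
    q = num / den  # m^3/s
    if q < 0:
        return math.nan
    return q / ml_min_to_m3_s(1.0)


def scan_safe_time(
    cfg: SystemConfig,
    W: float,
    tin_c: np.ndarray | list,
    q_ml_min: np.ndarray | list,
    threshold_min: float = DOSE_THRESHOLD_MIN,
    tail_taus: float = 10.0,
) -> pd.DataFrame:
    """Safe firing time over an (irrigation temperature, flow) grid.

    Returns a long-format table with columns ``t_in_c``, ``flow_ml_min``,
    ``tf_safe_min`` (``inf`` in the no-dose regime), ``regime``,
    ``tstar_c``, and per-row analytic contour locations ``q_tstar37_ml_min``
    and ``q_tstar43_ml_min`` — the flows at which the steady state crosses
    37 and 43 degC for that irrigation temperature (independent of the
    vessel volume).
    """
    tin_c = np.asarray(tin_c, dtype=float)
    q_ml_min = np.asarray(q_ml_min, dtype=float)
    if tin_c.size == 0 or q_ml_min.size == 0:
        raise ValueError("grid axes must be non-empty")

    rows = []
    for tin in tin_c:
        q37 = _q_at_tstar(cfg, W, tin, 37.0)
        q43 = _q_at_tstar(cfg, W, tin, 43.0)
        for q in q_ml_min:
            c = cfg.replace(Tin=tin, Q=ml_min_to_m3_s(q))
            res = safe_firing_time(c, W, threshold_min=threshold_min, tail_taus=tail_taus)
            rows.append(
                {
                    "t_in_c": tin,
                    "flow_ml_min": q,
                    "tf_safe_min": res.tf_safe_min,
                    "regime": res.regime,
                    "tstar_c": res.tstar_on,
                    "q_tstar37_ml_min": q37,
                    "q_tstar43_ml_min": q43,
                }
            )
    return pd.DataFrame(rows)
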