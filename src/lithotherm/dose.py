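"""Cumulative equivalent minutes at 43 degC (the t43 thermal-dose metric).

A temperature history ``T(t)`` is converted to the equivalent duration at a
constant 43 degC by::

    t43 = integral R(T)^(43 - T(t)) dt        [minutes]

with the piecewise base::

    R = 0     for T <= 37 degC   (no dose accrues)
        0.25  for 37 < T < 43 degC
        0.5   for T >= 43 degC

A curve held at exactly 43 degC for ``t`` minutes gives ``t43 = t``; every
degree above 43 doubles the accrual rate.  The conventional threshold for
tissue damage is ``t43 = 120`` minutes.

Analytic model curves are integrated by adaptive quadrature phase by phase
(with the 37 and 43 degC crossing times supplied as breakpoints); sampled
thermocouple traces use the composite trapezoid rule on the integrand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.integrate import quad

from .core import AnalyticCurve, LaserSchedule, SystemConfig, TemperatureTrace, _Phase

__all__ = ["DoseResult", "r_factor", "t43_of_curve", "t43_of_model", "DOSE_THRESHOLD_MIN"]

#: conventional tissue-damage threshold, equivalent minutes at 43 degC
DOSE_THRESHOLD_MIN = 120.0

_T_NO_DOSE = 37.0
_T_REF = 43.0
#: fallback tail length (s) past the last off-time when no time constant exists
_DEGENERATE_TAIL_S = 600.0
#: default tail length in units of the final-phase time constant
DEFAULT_TAIL_TAUS = 10.0
#: relative quadrature tolerance
_EPSREL = 1e-8


@dataclass(frozen=True)
class DoseResult:
    """t43 dose with the integration horizon actually used.

    ``truncated`` means the horizon cut the integral while dose was still
    accruing (temperature above 37 degC at the horizon); the reported value
    is then a lower bound.
    """

    t43: float  # equivalent minutes at 43 degC
    horizon: float  # s, end of integration
    truncated: bool

    def __post_init__(self) -> None:
        if self.t43 < 0:
            raise ValueError("t43 must be >= 0")


def r_factor(T: float) -> float:
    """Piecewise dose base R: 0 below 37 degC, 0.25 up to 43 degC, 0.5 above."""
    if not math.isfinite(T):
        raise ValueError("temperature must be finite")
    if T <= _T_NO_DOSE:
        return 0.0
    if T < _T_REF:
        return 0.25
    return 0.5


def _rate(T: np.ndarray) -> np.ndarray:
    """Vectorised dose accrual rate R^(43 - T), in equivalent min per min."""
    T = np.asarray(T, dtype=float)
    expo = _T_REF - T
    out = np.where(T >= _T_REF, 0.5 ** expo, 0.25 ** expo)
    return np.where(T <= _T_NO_DOSE, 0.0, out)


def _phase_crossing(ph: _Phase, level: float) -> float | None:
    """Time (absolute, s) at which a phase's exponential crosses ``level``."""
    if ph.Tstar is None:
        if ph.slope == 0.0:
            return None
        t = ph.t_start + (level - ph.T_start) / ph.slope
    else:
        num = ph.T_start - ph.Tstar
        den = level - ph.Tstar
        if num == 0.0 or den == 0.0 or (num > 0) != (den > 0):
            return None
        ratio = num / den
        if ratio <= 1.0:
            return None
        t = ph.t_start + ph.tau * math.log(ratio)
    if ph.t_start < t < ph.t_end:
        return t
    return None


def _auto_horizon(curve: AnalyticCurve, tail_taus: float) -> tuple[float, bool]:
    """Integration end for a model curve: where T falls to 37 degC, or a cut tail.

    Returns ``(horizon_s, truncated)``.  If the trailing (laser-off) phase
    relaxes below 37 degC the horizon is the exact crossing and the dose
    integral is complete.  Otherwise the asymptote stays above 37 degC, the
    tail contribution diverges, and the horizon is cut ``tail_taus`` time
    constants after the phase start (or a fixed tail when no time constant
    exists) with ``truncated = True``.
    """
    tail = curve.phases[-1]
    cross = _phase_crossing(tail, _T_NO_DOSE)
    if cross is not None:
        # crossing going down ends the dose; going up means a diverging tail
        going_down = (tail.Tstar is not None and tail.Tstar < _T_NO_DOSE) or (
            tail.Tstar is None and (tail.slope or 0.0) < 0.0
        )
        if going_down:
            return cross, False
    # no downward crossing: either the whole tail is already <= 37 (done) or
    # it stays/ends above 37 (diverges)
    if tail.Tstar is not None:
        limit = tail.Tstar
        start_below = tail.T_start <= _T_NO_DOSE
        if limit <= _T_NO_DOSE and start_below and cross is None:
            return tail.t_start, False
        horizon = tail.t_start + tail_taus * tail.tau
    else:
        if tail.T_start <= _T_NO_DOSE and (tail.slope or 0.0) <= 0.0:
            return tail.t_start, False
        horizon = tail.t_start + _DEGENERATE_TAIL_S
    truncated = float(curve(horizon)) > _T_NO_DOSE
    return horizon, truncated


def _t43_trace(trace: TemperatureTrace, t_start: float, horizon: float) -> DoseResult:
    times, temps = trace.times, trace.temps
    if t_start < times[0] - 1e-9 or horizon > times[-1] + 1e-9:
        raise ValueError(
            f"trace spans [{times[0]}, {times[-1]}] s but dose window "
            f"[{t_start}, {horizon}] s was requested"
        )
    inside = (times > t_start) & (times < horizon)
    t = np.concatenate(([t_start], times[inside], [horizon]))
    T = np.concatenate(
        ([np.interp(t_start, times, temps)], temps[inside], [np.interp(horizon, times, temps)])
    )
    t43 = float(np.trapezoid(_rate(T), t)) / 60.0
    truncated = bool(T[-1] > _T_NO_DOSE)
    return DoseResult(t43=max(t43, 0.0), horizon=horizon, truncated=truncated)


def _t43_analytic(curve: AnalyticCurve, t_start: float, horizon: float, truncated: bool) -> DoseResult:
    total = 0.0
    for ph in curve.phases:
        lo = max(ph.t_start, t_start)
        hi = min(ph.t_end, horizon)
        if hi <= lo:
            continue
        pts = sorted(
            x
            for x in (_phase_crossing(ph, _T_NO_DOSE), _phase_crossing(ph, _T_REF))
            if x is not None and lo < x < hi
        )
        # skip sub-intervals entirely at or below 37 degC (rate identically 0)
        edges = [lo, *pts, hi]
        for a, b in zip(edges[:-1], edges[1:]):
            mid = 0.5 * (a + b)
            if float(ph.temperature(mid)) <= _T_NO_DOSE:
                continue
            val, _ = quad(
                lambda t: float(_rate(ph.temperature(t))),
                a,
                b,
                epsrel=_EPSREL,
                epsabs=1e-12,
                limit=200,
            )
            total += val
    return DoseResult(t43=max(total / 60.0, 0.0), horizon=horizon, truncated=truncated)


Curve = Union[TemperatureTrace, AnalyticCurve, Callable[[float], float]]


def t43_of_curve(
    curve: Curve,
    t_start: float | None = None,
    horizon: float | None = None,
    tail_taus: float = DEFAULT_TAIL_TAUS,
) -> DoseResult:
    """t43 dose of a temperature curve, in equivalent minutes at 43 degC.

    Parameters
    ----------
    curve
        A :class:`TemperatureTrace` (trapezoid on the samples), an
        :class:`AnalyticCurve` (adaptive quadrature per analytic phase), or
        any callable ``T(t)`` in seconds (plain adaptive quadrature; both
        ``t_start`` and ``horizon`` are then required).
    t_start
        Integration start, s.  Defaults to the first laser-on time for a
        model curve and the first sample for a trace.
    horizon
        Integration end, s.  For a model curve the default integrates
        through firing and cool-down, stopping exactly where the
        temperature falls to 37 degC (dose rate becomes zero); when the
        off-phase asymptote stays above 37 degC the integral diverges and
        is cut ``tail_taus`` time constants into the trailing phase, with
        ``truncated=True``.
    """
    if isinstance(curve, TemperatureTrace):
        t0 = float(curve.times[0]) if t_start is None else float(t_start)
        t1 = float(curve.times[-1]) if horizon is None else float(horizon)
        if not t1 > t0:
            raise ValueError("horizon must exceed t_start")
        return _t43_trace(curve, t0, t1)

    if isinstance(curve, AnalyticCurve):
        if t_start is None:
            t_start = curve.schedule.t_first_on if curve.schedule.intervals else 0.0
        if horizon is None:
            horizon, truncated = _auto_horizon(curve, tail_taus)
            horizon = max(horizon, t_start)
        else:
            horizon = float(horizon)
            truncated = float(curve(horizon)) > _T_NO_DOSE
        if horizon <= t_start:
            return DoseResult(t43=0.0, horizon=float(t_start), truncated=truncated)
        return _t43_analytic(curve, float(t_start), horizon, truncated)

    if callable(curve):
        if t_start is None or horizon is None:
            raise ValueError("t_start and horizon are required for a bare callable")
        if not horizon > t_start:
            raise ValueError("horizon must exceed t_start")
        val, _ = quad(
            lambda t: float(_rate(np.asarray(curve(t)))),
            t_start,
            horizon,
            epsrel=_EPSREL,
            epsabs=1e-12,
            limit=500,
        )
        truncated = float(np.asarray(curve(horizon))) > _T_NO_DOSE
        return DoseResult(t43=max(val / 60.0, 0.0), horizon=float(horizon), truncated=truncated)

    raise TypeError(f"unsupported curve type: {type(curve)!r}")


def t43_of_model(
    cfg: SystemConfig,
    schedule: LaserSchedule,
    T_init: float | None = None,
    t_start: float | None = None,
    horizon: float | None = None,
    tail_taus: float = DEFAULT_TAIL_TAUS,
) -> DoseResult:
    """t43 of the analytic model solution for a config and firing schedule."""
    return t43_of_curve(
        AnalyticCurve(cfg, schedule, T_init), t_start=t_start, horizon=horizon, tail_taus=tail_taus
    )
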