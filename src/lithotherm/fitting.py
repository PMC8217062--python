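"""Least-squares estimation of the wall heat-loss coefficient beta.

``beta`` (heat-transfer coefficient times wall area, W/degC) depends on the
vessel material and geometry and cannot be tabulated; it is estimated by
fitting the analytic temperature solution to measured thermocouple traces.
The canonical identification protocol is the still-fluid, high-power case
(no irrigation, 40 W): there the rise curve
``T0 + (W/beta)(1 - exp(-beta t / (rho c V)))`` depends on ``beta`` alone.

The fit minimises the summed squared residual between the model curve and
all trace samples inside the fit window (laser-on to laser-off by default)
with bounded scalar minimisation; a coarse log-spaced scan first checks
that the objective is identifiable and unimodal.  The standard error is
curvature-based: ``var(beta) = 2 * sigma^2 / d2RSS/dbeta2`` with the noise
variance estimated from the residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .core import AnalyticCurve, LaserSchedule, SystemConfig, TemperatureTrace

__all__ = ["FitResult", "NonIdentifiableError", "fit_beta", "BETA_BOUNDS"]

#: search bounds for beta, W/degC
BETA_BOUNDS = (1e-3, 1e2)
_XATOL = 1e-6


class NonIdentifiableError(ValueError):
    """The data carry no information about beta (flat objective)."""


@dataclass(frozen=True)
class FitResult:
    """Estimated wall heat-loss coefficient with fit diagnostics."""

    beta_hat: float  # W/degC
    rss: float  # degC^2, summed squared residual at the optimum
    n_points: int
    stderr_beta: float  # W/degC, curvature-based
    window: tuple[float, float]  # s, fit window actually used
    bound_hit: bool = False

    def __post_init__(self) -> None:
        if not self.beta_hat > 0:
            raise ValueError("beta_hat must be > 0")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")


def _pool_window(
    traces: Sequence[TemperatureTrace], window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window
    ts, ys = [], []
    for tr in traces:
        m = (tr.times >= lo) & (tr.times <= hi)
        ts.append(tr.times[m])
        ys.append(tr.temps[m])
    return np.concatenate(ts), np.concatenate(ys)


def fit_beta(
    traces: Sequence[TemperatureTrace],
    cfg_known: SystemConfig,
    schedule: LaserSchedule,
    window: tuple[float, float] | None = None,
    T_init: float | None = None,
) -> FitResult:
    """Estimate beta from one or more temperature traces.

    Parameters
    ----------
    traces
        Thermocouple traces covering (at least part of) the fit window;
        multiple probes or repeated runs are pooled with equal weight.
    cfg_known
        System configuration with every parameter except ``beta`` taken as
        known; its ``beta`` field is ignored.
    schedule
        The firing schedule used during acquisition.
    window
        Fit window in seconds; defaults to (first laser-on, last laser-off),
        i.e. the temperature-rise phase.

    Raises
    ------
    NonIdentifiableError
        If the pooled data inside the window are insensitive to beta (e.g.
        flat traces with the laser off and no irrigation).
    """
    if not traces:
        raise ValueError("at least one trace is required")
    if window is None:
        window = (schedule.t_first_on, schedule.t_last_off)
    lo, hi = float(window[0]), float(window[1])
    if not hi > lo:
        raise ValueError("fit window must have positive length")

    t_pool, y_pool = _pool_window(traces, (lo, hi))
    if t_pool.size < 3:
        raise ValueError(
            f"only {t_pool.size} trace samples fall inside the fit window [{lo}, {hi}] s"
        )

    def rss(beta: float) -> float:
        curve = AnalyticCurve(cfg_known.replace(beta=beta), schedule, T_init)
        r = curve(t_pool) - y_pool
        return float(r @ r)

    # identifiability / unimodality pre-scan on a log grid
    scan_b = np.logspace(math.log10(BETA_BOUNDS[0]), math.log10(BETA_BOUNDS[1]), 25)
    scan_rss = np.array([rss(b) for b in scan_b])
    spread = scan_rss.max() - scan_rss.min()
    if not spread > 1e-9 * max(scan_rss.max(), 1.0):
        raise NonIdentifiableError(
            "the objective is flat in beta over the search range; the data "
            "show no observable response to wall heat loss (is the laser on "
            "and is there a temperature gradient?)"
        )
    sign_changes = int(np.sum(np.diff(np.sign(np.diff(scan_rss))) != 0))
    if sign_changes > 1:
        warnings.warn(
            "beta objective is not unimodal on the coarse scan; the bounded "
            "minimiser may return a local optimum",
            stacklevel=2,
        )

    res = minimize_scalar(rss, bounds=BETA_BOUNDS, method="bounded", options={"xatol": _XATOL})
    beta_hat = float(res.x)
    rss_min = float(res.fun)

    rel = (beta_hat - BETA_BOUNDS[0]) / (BETA_BOUNDS[1] - BETA_BOUNDS[0])
    bound_hit = rel < 1e-5 or rel > 1 - 1e-5
    if bound_hit:
        warnings.warn(
            f"beta estimate {beta_hat:.4g} W/degC sits at a search bound "
            f"{BETA_BOUNDS}; treat the fit with suspicion",
            stacklevel=2,
        )

    # curvature-based standard error
    h = max(1e-5, 1e-4 * beta_hat)
    d2 = (rss(beta_hat + h) - 2.0 * rss_min + rss(beta_hat - h)) / (h * h)
    n = int(t_pool.size)
    sigma2 = rss_min / max(n - 1, 1)
    stderr = math.sqrt(2.0 * sigma2 / d2) if d2 > 0 else math.inf

    return FitResult(
        beta_hat=beta_hat,
        rss=rss_min,
        n_points=n,
        stderr_beta=stderr,
        window=(lo, hi),
        bound_hit=bound_hit,
    )
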