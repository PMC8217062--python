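"""Lumped-capacitance thermal model of an irrigated vessel heated by a surgical laser.

The vessel (a fluid-filled cavity such as the renal pelvis, or an in vitro
test cell) is treated as a single well-mixed compartment of volume ``V``
containing fluid with density ``rho`` and specific heat ``c``.  Three energy
fluxes act on it:

* laser power ``W`` deposited into the fluid while the laser fires,
* advective exchange with irrigation inflow at rate ``Q`` and temperature
  ``Tin`` (perfect mixing, outflow at the vessel temperature),
* Newton cooling through the vessel wall to a surrounding bath at ``T0``
  with an effective wall conductance ``beta`` (heat-transfer coefficient
  times exchange area, W/degC).

The balance is the linear ODE::

    rho*c*V * dT/dt = W(t) + rho*c*Q * (Tin - T) - beta * (T - T0)

Within any phase of constant laser power the solution is an exponential
relaxation ``T(t) = Tstar + (T_start - Tstar) * exp(-(t - t_start)/tau)``
towards the phase steady state::

    Tstar = (W + rho*c*Q*Tin + beta*T0) / (rho*c*Q + beta)
    tau   = rho*c*V / (rho*c*Q + beta)

``Tstar`` is independent of the vessel volume; ``tau`` is proportional to
it.  A full firing schedule (arbitrary on/off duty cycle) is propagated
phase by phase with temperature continuity at every switch.

When ``Q = 0`` and ``beta = 0`` there is no heat sink: no steady state
exists and the temperature ramps linearly at ``W/(rho*c*V)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "FluidProperties",
    "SystemConfig",
    "LaserSchedule",
    "TemperatureTrace",
    "AnalyticCurve",
    "UnboundedHeatingError",
    "heat_load",
    "temperature_at",
    "temperature_trace",
    "ode_oracle",
    "delta_T_after_firing",
    "ml_to_m3",
    "ml_min_to_m3_s",
]

#: volume of one millilitre in cubic metres
ML = 1e-6
#: one millilitre per minute in cubic metres per second
ML_PER_MIN = 1e-6 / 60.0


def ml_to_m3(volume_ml: float) -> float:
    """Convert a clinical volume in mL to SI cubic metres."""
    return volume_ml * ML


def ml_min_to_m3_s(flow_ml_min: float) -> float:
    """Convert a clinical irrigation rate in mL/min to SI m^3/s."""
    return flow_ml_min * ML_PER_MIN


class UnboundedHeatingError(ValueError):
    """No steady state exists: the vessel has no heat sink (Q = 0 and beta = 0)."""


@dataclass(frozen=True)
class FluidProperties:
    """Thermal constants of the irrigation fluid.

    Defaults are water near room temperature: conductivity
    ``k = 0.606 W/(m K)``, density ``rho = 1000 kg/m^3`` and specific heat
    ``c = 4180 J/(kg K)``.  ``k`` does not enter the lumped solution (no
    spatial gradients are resolved) but is carried for configuration
    fidelity.
    """

    k: float = 6.06e-1
    rho: float = 1.00e3
    c: float = 4.18e3

    def __post_init__(self) -> None:
        for name in ("k", "rho", "c"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"FluidProperties.{name} must be finite and > 0, got {v!r}")

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho*c in J/(m^3 K)."""
        return self.rho * self.c


WATER = FluidProperties()


@dataclass(frozen=True)
class SystemConfig:
    """Vessel, bath and irrigation configuration, in SI units.

    Parameters
    ----------
    V : float
        Vessel volume, m^3.
    T0 : float
        Bath temperature, degC; also the default initial fluid temperature.
    beta : float
        Effective wall heat-loss conductance (heat-transfer coefficient
        times wall area), W/degC.
    Q : float
        Irrigation flow rate, m^3/s.
    Tin : float
        Irrigation fluid temperature, degC.
    fluid : FluidProperties
        Thermal constants of the fluid (water by default).

    Use :meth:`from_clinical` to construct from mL and mL/min.
    """

    V: float
    T0: float
    beta: float
    Q: float = 0.0
    Tin: float | None = None
    fluid: FluidProperties = field(default_factory=FluidProperties)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.V) and self.V > 0):
            raise ValueError(f"V must be finite and > 0, got {self.V!r}")
        if not (math.isfinite(self.Q) and self.Q >= 0):
            raise ValueError(f"Q must be finite and >= 0, got {self.Q!r}")
        if not (math.isfinite(self.beta) and self.beta >= 0):
            raise ValueError(f"beta must be finite and >= 0, got {self.beta!r}")
        if not math.isfinite(self.T0):
            raise ValueError("T0 must be finite")
        if self.Tin is None:
            object.__setattr__(self, "Tin", self.T0)
        if not math.isfinite(self.Tin):  # type: ignore[arg-type]
            raise ValueError("Tin must be finite")

    @classmethod
    def from_clinical(
        cls,
        volume_ml: float,
        t0_c: float,
        beta_w_per_c: float,
        flow_ml_min: float = 0.0,
        t_in_c: float | None = None,
        fluid: FluidProperties | None = None,
    ) -> "SystemConfig":
        """Build a config from clinical units (mL, mL/min, degC, W/degC)."""
        return cls(
            V=ml_to_m3(volume_ml),
            T0=t0_c,
            beta=beta_w_per_c,
            Q=ml_min_to_m3_s(flow_ml_min),
            Tin=t_in_c,
            fluid=fluid if fluid is not None else FluidProperties(),
        )

    def replace(self, **changes) -> "SystemConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    @property
    def heat_capacity(self) -> float:
        """Total heat capacity rho*c*V of the vessel contents, J/degC."""
        return self.fluid.volumetric_heat_capacity * self.V

    @property
    def loss_conductance(self) -> float:
        """Total linear loss conductance rho*c*Q + beta, W/degC."""
        return self.fluid.volumetric_heat_capacity * self.Q + self.beta


@dataclass(frozen=True)
class LaserSchedule:
    """Ordered, non-overlapping laser on-intervals ``(t_on, t_off, power)``.

    The classic single-burst protocol (laser on at ``t1``, off at ``t2``,
    firing time ``tf = t2 - t1``) is the one-interval case; arbitrary
    operator duty cycles are sequences of intervals.
    """

    intervals: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        iv = tuple((float(a), float(b), float(w)) for a, b, w in self.intervals)
        object.__setattr__(self, "intervals", iv)
        prev_off = 0.0
        for i, (on, off, w) in enumerate(iv):
            if not (0.0 <= on < off):
                raise ValueError(f"interval {i}: need 0 <= t_on < t_off, got ({on}, {off})")
            if on < prev_off:
                raise ValueError(f"interval {i} overlaps or is out of order (t_on={on} < previous t_off={prev_off})")
            if not (math.isfinite(w) and w >= 0):
                raise ValueError(f"interval {i}: power must be finite and >= 0, got {w}")
            prev_off = off

    @classmethod
    def single(cls, t_on: float, t_off: float, power: float) -> "LaserSchedule":
        """One firing burst from ``t_on`` to ``t_off`` at ``power`` watts."""
        return cls(intervals=((t_on, t_off, power),))

    @property
    def t_first_on(self) -> float:
        if not self.intervals:
            raise ValueError("empty schedule has no on-time")
        return self.intervals[0][0]

    @property
    def t_last_off(self) -> float:
        if not self.intervals:
            raise ValueError("empty schedule has no off-time")
        return self.intervals[-1][1]

    def power_at(self, t: float) -> float:
        """Laser power at time ``t`` (on-intervals are half-open [on, off))."""
        for on, off, w in self.intervals:
            if on <= t < off:
                return w
        return 0.0


IDLE = LaserSchedule(intervals=())


@dataclass
class TemperatureTrace:
    """A sampled (time, temperature) series, from the model or a thermocouple."""

    times: np.ndarray
    temps: np.ndarray
    label: str = "model"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temps = np.asarray(self.temps, dtype=float)
        if self.times.ndim != 1 or self.temps.ndim != 1:
            raise ValueError("times and temps must be one-dimensional")
        if self.times.size != self.temps.size:
            raise ValueError(f"length mismatch: {self.times.size} times vs {self.temps.size} temps")
        if self.times.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.temps))):
            raise ValueError("times and temps must be finite")

    def __len__(self) -> int:
        return int(self.times.size)

    def delta_T(self, t0: float) -> np.ndarray:
        """Temperature change relative to a reference temperature ``t0``."""
        return self.temps - t0


def heat_load(cfg: SystemConfig, W: float) -> tuple[float, float]:
    """Steady state and time constant of one constant-power phase.

    Returns ``(Tstar, tau)`` with::

        Tstar = (W + rho*c*Q*Tin + beta*T0) / (rho*c*Q + beta)
        tau   = rho*c*V / (rho*c*Q + beta)

    ``Tstar`` does not depend on the volume; ``tau`` is proportional to it.

    Raises
    ------
    UnboundedHeatingError
        If ``Q = 0`` and ``beta = 0``: with no sink the temperature ramps
        without bound and no steady state exists.
    """
    if not (math.isfinite(W) and W >= 0):
        raise ValueError(f"laser power must be finite and >= 0, got {W!r}")
    G = cfg.loss_conductance
    if G <= 0.0:
        raise UnboundedHeatingError(
            "no steady state: Q = 0 and beta = 0 leave the vessel with no heat sink"
        )
    rcQ = cfg.fluid.volumetric_heat_capacity * cfg.Q
    Tstar = (W + rcQ * cfg.Tin + cfg.beta * cfg.T0) / G
    tau = cfg.heat_capacity / G
    return Tstar, tau


@dataclass(frozen=True)
class _Phase:
    """One constant-power segment of the piecewise solution."""

    t_start: float
    t_end: float  # math.inf for the trailing phase
    power: float
    T_start: float
    Tstar: float | None  # None in the degenerate (no-sink) branch
    tau: float | None
    slope: float | None  # degC/s, degenerate branch only

    def temperature(self, t):
        """Evaluate the phase solution at time(s) ``t`` (>= t_start)."""
        dt = np.asarray(t, dtype=float) - self.t_start
        if self.Tstar is None:
            out = self.T_start + self.slope * dt
        else:
            out = self.Tstar + (self.T_start - self.Tstar) * np.exp(-dt / self.tau)
        return out

    @property
    def T_end(self) -> float:
        if not math.isfinite(self.t_end):
            raise ValueError("trailing phase has no end")
        return float(self.temperature(self.t_end))


class AnalyticCurve:
    """The piecewise-analytic temperature solution for one config and schedule.

    Callable on scalar or array times.  The pre-firing phase (laser off from
    ``t = 0`` to the first on-time) is part of the solution, so cold
    irrigation cools the vessel before firing starts.  Temperature is
    continuous across every switch.
    """

    def __init__(
        self,
        cfg: SystemConfig,
        schedule: LaserSchedule,
        T_init: float | None = None,
    ) -> None:
        self.cfg = cfg
        self.schedule = schedule
        self.T_init = cfg.T0 if T_init is None else float(T_init)
        self.phases = self._build_phases()
        self._starts = np.array([p.t_start for p in self.phases])

    def _build_phases(self) -> list[_Phase]:
        cfg = self.cfg
        segments: list[tuple[float, float, float]] = []
        cursor = 0.0
        for on, off, w in self.schedule.intervals:
            if on > cursor:
                segments.append((cursor, on, 0.0))
            segments.append((on, off, w))
            cursor = off
        segments.append((cursor, math.inf, 0.0))

        G = cfg.loss_conductance
        phases: list[_Phase] = []
        T = self.T_init
        for a, b, w in segments:
            if G > 0.0:
                Tstar, tau = heat_load(cfg, w)
                ph = _Phase(a, b, w, T, Tstar, tau, None)
            else:
                ph = _Phase(a, b, w, T, None, None, w / cfg.heat_capacity)
            phases.append(ph)
            if math.isfinite(b):
                T = ph.T_end
        return phases

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time must be >= 0")
        idx = np.searchsorted(self._starts, t_arr, side="right") - 1
        if t_arr.ndim == 0:
            return float(self.phases[int(idx)].temperature(t_arr))
        out = np.empty_like(t_arr)
        for i, ph in enumerate(self.phases):
            mask = idx == i
            if np.any(mask):
                out[mask] = ph.temperature(t_arr[mask])
        return out


def temperature_at(
    cfg: SystemConfig,
    schedule: LaserSchedule,
    t: float,
    T_init: float | None = None,
) -> float:
    """Volume-averaged temperature at time ``t`` under the given schedule.

    ``T_init`` defaults to the bath temperature ``cfg.T0`` (the fluid starts
    in equilibrium with the bath).
    """
    return AnalyticCurve(cfg, schedule, T_init)(float(t))


def temperature_trace(
    cfg: SystemConfig,
    schedule: LaserSchedule,
    t_grid: Sequence[float] | np.ndarray | None = None,
    T_init: float | None = None,
    label: str = "model",
) -> TemperatureTrace:
    """Sample the analytic solution on a time grid.

    The default grid is 0 to 100 s at 0.1 s spacing, matching a protocol of
    20 s irrigation-only lead-in, 60 s firing and 20 s cool-down recorded at
    thermocouple rate.
    """
    if t_grid is None:
        t_grid = np.arange(0.0, 100.0 + 1e-9, 0.1)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty time grid")
    if t_grid.size >= 2 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("time grid must be strictly increasing")
    curve = AnalyticCurve(cfg, schedule, T_init)
    return TemperatureTrace(times=t_grid, temps=curve(t_grid), label=label)


def delta_T_after_firing(cfg: SystemConfig, W: float, t_f: float) -> float:
    """Temperature change ``T(t_f) - T0`` after firing at ``W`` watts for ``t_f`` s.

    Firing starts at ``t = 0`` from the bath temperature.  The result can
    be negative when cold irrigation removes heat faster than the laser
    supplies it.
    """
    if not t_f > 0:
        raise ValueError(f"firing time must be > 0, got {t_f!r}")
    curve = AnalyticCurve(cfg, LaserSchedule.single(0.0, t_f, W))
    return float(curve(t_f)) - cfg.T0


def _rk4_phase(T0: float, a: float, b: float, duration: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Classical fixed-step RK4 for ``dT/dt = a - b*T`` over one phase.

    For a scalar linear ODE the RK4 update collapses to the affine
    recurrence ``T_{n+1} = T_n + dt*(a - b*T_n)*s`` with
    ``s = 1 - b*dt/2 + (b*dt)^2/6 - (b*dt)^3/24``, which is evaluated in
    closed form over the whole phase (mathematically identical to stepping,
    without the Python loop).  Returns node times (relative to phase start,
    including both endpoints) and temperatures.
    """
    n_full = int(math.floor(duration / dt + 1e-12))
    rem = duration - n_full * dt

    def growth(h: float) -> tuple[float, float]:
        z = b * h
        s = 1.0 - z / 2.0 + z * z / 6.0 - z ** 3 / 24.0
        g = 1.0 - z * s  # truncated exp(-z)
        return g, s

    times = [0.0]
    temps = [T0]
    if n_full > 0:
        g, s = growth(dt)
        n = np.arange(1, n_full + 1, dtype=float)
        if b == 0.0:
            T_nodes = T0 + a * dt * n
        else:
            Teq = a / b  # fixed point of the RK4 map equals the true steady state
            T_nodes = Teq + (T0 - Teq) * np.exp(n * math.log(g)) if g > 0 else Teq + (T0 - Teq) * g ** n
        times.extend((dt * n).tolist())
        temps.extend(np.atleast_1d(T_nodes).tolist())
    if rem > 1e-12:
        g, s = growth(rem)
        T_last = temps[-1]
        temps.append(g * T_last + a * rem * s)
        times.append(times[-1] + rem)
    return np.asarray(times), np.asarray(temps)


def ode_oracle(
    cfg: SystemConfig,
    schedule: LaserSchedule,
    t_grid: Sequence[float] | np.ndarray,
    dt: float = 1e-3,
    T_init: float | None = None,
) -> TemperatureTrace:
    """Fixed-step RK4 integration of the energy balance, for verification.

    Integrates ``rho*c*V dT/dt = W(t) + rho*c*Q (Tin - T) - beta (T - T0)``
    phase by phase at step ``dt`` (a shortened final step aligns each phase
    boundary exactly) and linearly interpolates onto ``t_grid``.  Converges
    to the analytic solution at fourth order in ``dt``; used only as an
    independent check of :func:`temperature_trace`.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty time grid")
    if np.any(t_grid < 0):
        raise ValueError("time must be >= 0")
    T_init = cfg.T0 if T_init is None else float(T_init)

    t_max = float(t_grid[-1])
    rcV = cfg.heat_capacity
    rcQ = cfg.fluid.volumetric_heat_capacity * cfg.Q
    b_coef = cfg.loss_conductance / rcV

    # phase boundaries clipped to [0, t_max]
    bounds = [0.0]
    for on, off, _ in schedule.intervals:
        for x in (on, off):
            if 0.0 < x < t_max:
                bounds.append(x)
    bounds.append(t_max)
    bounds = sorted(set(bounds))

    all_t = [np.array([0.0])]
    all_T = [np.array([T_init])]
    T = T_init
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        w = schedule.power_at(0.5 * (lo + hi))
        a_coef = (w + rcQ * cfg.Tin + cfg.beta * cfg.T0) / rcV
        ts, Ts = _rk4_phase(T, a_coef, b_coef, hi - lo, dt)
        all_t.append(lo + ts[1:])
        all_T.append(Ts[1:])
        T = float(Ts[-1])
    t_nodes = np.concatenate(all_t)
    T_nodes = np.concatenate(all_T)
    temps = np.interp(t_grid, t_nodes, T_nodes)
    if t_grid.size < 2:
        t_grid = np.array([t_grid[0], t_grid[0] + dt])
        temps = np.array([temps[0], temps[0]])
    return TemperatureTrace(times=t_grid, temps=temps, label="ode-oracle")
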