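"""Lumped-parameter model (LPM) of temperature evolution in a wet stirred media mill.

Wet stirred media milling (nanomilling) converts most of the stirrer's shaft
work into heat, so the suspension temperature at the mill outlet rises until
heat removal through the chilled jacket balances generation.  Treating the
mill charge (beads + suspension + stirrer element) as a single lumped thermal
mass with constant apparent heat generation rate ``Q_gen`` and apparent
heat-transfer product ``UA`` gives the transient enthalpy balance

    m*Cp * dT/dt = Q_gen - UA * (T - T_ch)

whose closed-form solution, with T(0) = T_0, is

    T(t) = (T_ch + Q_gen/UA) + (T_0 - T_ch - Q_gen/UA) * exp(-UA*t / (m*Cp))

an exponential approach toward the steady state ``T_ch + Q_gen/UA`` with time
constant ``m*Cp / UA``.  All times are minutes, temperatures are degrees
Celsius, ``Q_gen`` is J/min and ``UA`` is J/(min °C).

This module holds the domain types, the forward model (analytic and ODE
forms), the lumped heat capacity lookup, threshold-crossing times, and the
Gompertz correlation for the early temperature rise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConvergenceError, DomainError, ExtrapolationWarning

__all__ = [
    "MAX_PACKING_FRACTION",
    "DEFAULT_CHILLER_TEMP_C",
    "MCP_ANCHOR_LOADINGS",
    "MCP_ANCHOR_VALUES",
    "UNREACHABLE",
    "ProcessCondition",
    "LPMParams",
    "ThermalSystem",
    "TemperatureProfile",
    "GompertzModel",
    "mill_heat_capacity",
    "simulate_temperature",
    "simulate_ode",
    "steady_state_temperature",
    "time_to_temperature",
    "gompertz_trise",
]

#: Maximum packing limit of randomly packed monodisperse spherical beads.
MAX_PACKING_FRACTION = 0.63

#: Default chiller set-point, °C.
DEFAULT_CHILLER_TEMP_C = 6.1

#: Bead loadings (volume fraction) at which the lumped heat capacity of the
#: mill charge was computed from the component masses and specific heats.
MCP_ANCHOR_LOADINGS = np.array([0.35, 0.40, 0.45, 0.50, 0.55, 0.60])
#: Lumped heat capacity of the mill charge at the anchor loadings, J/°C.
MCP_ANCHOR_VALUES = np.array([470.9, 465.6, 460.4, 455.2, 450.0, 444.8])

#: Sentinel returned by :func:`time_to_temperature` when the target lies
#: beyond the steady-state asymptote (infinite time to reach it).
UNREACHABLE = math.inf


@dataclass(frozen=True)
class ProcessCondition:
    """Settings of one milling run.

    Parameters
    ----------
    omega : float
        Stirrer speed, rpm.
    c : float
        Bead loading, volume fraction of the chamber occupied by bulk beads.
        Physically capped below ~0.63 (random close packing).
    d_b : float
        Bead size, µm.
    run_id : str
        Optional label for the run.
    """

    omega: float
    c: float
    d_b: float
    run_id: str = ""

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise DomainError(f"stirrer speed must be positive, got {self.omega}")
        if not 0 < self.c < MAX_PACKING_FRACTION:
            raise DomainError(
                f"bead loading must lie in (0, {MAX_PACKING_FRACTION}), got {self.c}"
            )
        if not self.d_b > 0:
            raise DomainError(f"bead size must be positive, got {self.d_b}")


@dataclass(frozen=True)
class LPMParams:
    """The two fitted parameters of the lumped-parameter model.

    ``q_gen`` is the apparent heat generation rate (J/min) and ``ua`` the
    apparent overall heat transfer coefficient times surface area
    (J/(min °C)).  Both are fitting parameters in a time-averaged,
    statistical sense, not first-principles quantities.
    """

    q_gen: float
    ua: float

    def __post_init__(self) -> None:
        if not self.q_gen >= 0:
            raise DomainError(f"q_gen must be non-negative, got {self.q_gen}")
        if not self.ua > 0:
            raise DomainError(f"ua must be positive, got {self.ua}")


@dataclass(frozen=True)
class ThermalSystem:
    """Lumped thermal constants of the mill charge.

    Parameters
    ----------
    mcp : float
        Lumped heat capacity of the charge, J/°C.  Only the product m*Cp
        enters the model, so mass and specific heat are never stored
        separately.
    t_ch : float
        Chiller temperature, °C.
    t_0 : float, optional
        Initial mill-outlet temperature, °C.  It is a property of each run
        (experimentally it varied over a narrow 13-18 °C range), so it may be
        left ``None`` and supplied by the profile being fitted.
    """

    mcp: float
    t_ch: float = DEFAULT_CHILLER_TEMP_C
    t_0: float | None = None

    def __post_init__(self) -> None:
        if not self.mcp > 0:
            raise DomainError(f"mcp must be positive, got {self.mcp}")
        if self.t_0 is not None and self.t_0 < self.t_ch:
            warnings.warn(
                f"initial temperature {self.t_0} °C below chiller temperature "
                f"{self.t_ch} °C; all observed runs start above the chiller",
                UserWarning,
                stacklevel=2,
            )

    def require_t0(self) -> float:
        if self.t_0 is None:
            raise DomainError("this operation needs an initial temperature t_0")
        return self.t_0


class TemperatureProfile:
    """A sampled time-temperature trajectory at the mill outlet.

    ``times`` are minutes (strictly increasing, non-negative) and ``temps``
    degrees Celsius, of equal length.
    """

    __slots__ = ("times", "temps")

    def __init__(self, times: Sequence[float], temps: Sequence[float]):
        times = np.asarray(times, dtype=float)
        temps = np.asarray(temps, dtype=float)
        if times.ndim != 1 or temps.ndim != 1:
            raise DomainError("times and temps must be one-dimensional")
        if times.size != temps.size:
            raise DomainError(
                f"length mismatch: {times.size} times vs {temps.size} temperatures"
            )
        if times.size == 0:
            raise DomainError("profile must contain at least one sample")
        if times[0] < 0:
            raise DomainError("times must be non-negative")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise DomainError("times must be strictly increasing")
        self.times = times
        self.temps = temps

    def __len__(self) -> int:
        return int(self.times.size)

    def __repr__(self) -> str:
        return (
            f"TemperatureProfile(n={len(self)}, t=[{self.times[0]:g}, "
            f"{self.times[-1]:g}] min, T=[{self.temps.min():.2f}, "
            f"{self.temps.max():.2f}] °C)"
        )

    @property
    def t_0(self) -> float:
        """Initial temperature: the first sampled value, °C."""
        return float(self.temps[0])

    def to_frame(self):
        """Return the profile as a two-column pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame({"time_min": self.times, "temperature_C": self.temps})


@dataclass(frozen=True)
class GompertzModel:
    """Gompertz growth correlation ``T_rise = A * exp(-exp(b - r*Q_gen))``.

    ``amplitude`` (A, °C) is the saturation rise, ``shift`` (b, dimensionless)
    locates the inflection, and ``rate`` (r, per J/min) sets how fast the rise
    saturates with the heat generation rate.
    """

    amplitude: float
    shift: float
    rate: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise DomainError(f"amplitude must be positive, got {self.amplitude}")
        if not self.rate > 0:
            raise DomainError(f"rate must be positive, got {self.rate}")


def mill_heat_capacity(c: float) -> float:
    """Lumped heat capacity m*Cp of the mill charge at bead loading ``c``, J/°C.

    The anchor values were computed from the masses and specific heats of the
    beads, the drug suspension and the stirrer element at six bead loadings
    (0.35-0.60); between anchors the dependence is linear to within the
    printed precision, so intermediate loadings are answered by linear
    interpolation.  Outside [0.35, 0.60] the ends are extrapolated linearly
    with an :class:`ExtrapolationWarning`; loadings outside (0, 0.63) are a
    :class:`DomainError` (beyond the bead packing limit).
    """
    if not 0 < c < MAX_PACKING_FRACTION:
        raise DomainError(
            f"bead loading must lie in (0, {MAX_PACKING_FRACTION}), got {c}"
        )
    lo, hi = MCP_ANCHOR_LOADINGS[0], MCP_ANCHOR_LOADINGS[-1]
    if c < lo or c > hi:
        warnings.warn(
            f"bead loading {c} outside the tabulated range [{lo}, {hi}]; "
            "extrapolating the heat capacity linearly",
            ExtrapolationWarning,
            stacklevel=2,
        )
        if c < lo:
            i0, i1 = 0, 1
        else:
            i0, i1 = -2, -1
        x0, x1 = MCP_ANCHOR_LOADINGS[i0], MCP_ANCHOR_LOADINGS[i1]
        y0, y1 = MCP_ANCHOR_VALUES[i0], MCP_ANCHOR_VALUES[i1]
        return float(y0 + (y1 - y0) * (c - x0) / (x1 - x0))
    return float(np.interp(c, MCP_ANCHOR_LOADINGS, MCP_ANCHOR_VALUES))


def _as_time_grid(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise DomainError("times must be a non-empty 1-D sequence")
    if t[0] < 0:
        raise DomainError("times must be non-negative")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise DomainError("times must be strictly increasing")
    return t


def simulate_temperature(
    params: LPMParams, system: ThermalSystem, times: Sequence[float]
) -> TemperatureProfile:
    """Evaluate the closed-form temperature trajectory on a time grid.

    Returns the exponential approach from ``t_0`` toward the steady state
    ``t_ch + q_gen/ua`` with time constant ``mcp/ua`` minutes.
    """
    t = _as_time_grid(times)
    t0 = system.require_t0()
    t_ss = system.t_ch + params.q_gen / params.ua
    temps = t_ss + (t0 - t_ss) * np.exp(-params.ua * t / system.mcp)
    return TemperatureProfile(t, temps)


def simulate_ode(
    params: LPMParams,
    system: ThermalSystem,
    times: Sequence[float],
    tol: float = 1e-9,
) -> TemperatureProfile:
    """Integrate the enthalpy-balance ODE numerically on a time grid.

    Exists as an independent route to the same trajectory as
    :func:`simulate_temperature`; the two agree to integration tolerance.
    """
    t = _as_time_grid(times)
    t0 = system.require_t0()

    def rhs(_t: float, temp: np.ndarray) -> np.ndarray:
        return (params.q_gen - params.ua * (temp - system.t_ch)) / system.mcp

    sol = solve_ivp(
        rhs,
        (0.0, float(t[-1])) if t[-1] > 0 else (0.0, 1.0),
        [t0],
        t_eval=t,
        method="DOP853",
        rtol=tol,
        atol=tol,
    )
    if not sol.success:
        raise ConvergenceError(f"ODE integration failed: {sol.message}")
    return TemperatureProfile(t, sol.y[0])


def steady_state_temperature(
    params: LPMParams, t_ch: float = DEFAULT_CHILLER_TEMP_C
) -> float:
    """Asymptotic mill-outlet temperature ``t_ch + q_gen/ua``, °C."""
    if not params.ua > 0:
        raise DomainError("ua must be positive")
    return t_ch + params.q_gen / params.ua


def time_to_temperature(
    params: LPMParams, system: ThermalSystem, t_target: float
) -> float:
    """Time in minutes at which the trajectory first reaches ``t_target``.

    Inverts the closed-form solution:
    ``t = (mcp/ua) * ln((T_ss - t_0) / (T_ss - t_target))`` on the heating
    branch, and symmetrically when cooling.  Targets on the far side of the
    steady-state asymptote (or behind the starting point) are never reached;
    those return the :data:`UNREACHABLE` sentinel rather than raising, so
    design-space sweeps can proceed.
    """
    t0 = system.require_t0()
    t_ss = steady_state_temperature(params, system.t_ch)
    if t_target == t0:
        return 0.0
    if t0 == t_ss:
        return UNREACHABLE  # constant profile never leaves t_0
    heating = t0 < t_ss
    if heating and not (t0 < t_target < t_ss):
        return UNREACHABLE
    if not heating and not (t_ss < t_target < t0):
        return UNREACHABLE
    return float((system.mcp / params.ua) * math.log((t_ss - t0) / (t_ss - t_target)))


def gompertz_trise(model: GompertzModel, q_gen: float) -> float:
    """Temperature rise at 6 min predicted by the Gompertz correlation, °C.

    Monotone increasing in ``q_gen`` and bounded above by the amplitude.
    """
    if q_gen < 0:
        raise DomainError(f"q_gen must be non-negative, got {q_gen}")
    return float(model.amplitude * math.exp(-math.exp(model.shift - model.rate * q_gen)))
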