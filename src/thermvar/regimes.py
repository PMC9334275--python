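"""Generators for the experimental water-temperature regimes.

The fluctuating treatments alternate the heater set point between the band's
minimum and maximum every half cycle (one week for the default two-week
cycle), and the bath takes roughly half a day to track a set-point change.
The resulting profile is a symmetric trapezoidal wave: a linear ramp of
``ramp_hours`` after each switch, then a hold at the new set point.  Because
up- and down-ramps have equal duration the time mean is exactly the midpoint
``(t_min + t_max) / 2`` regardless of ramp length.

The four treatment bands share a 23 °C mean: constant 23, low 22–24,
medium 21–25, and high 20–26 °C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DesignError, DomainError
from .tpc import TemperatureProfile

__all__ = [
    "RegimeSpec",
    "make_regime",
    "regime_mean",
    "TREATMENT_REGIMES",
    "read_profile",
    "write_profile",
]


@dataclass(frozen=True)
class RegimeSpec:
    """Specification of a constant or trapezoidal fluctuating regime.

    ``cycle_days`` is the length of one full warm+cold cycle (default two
    weeks); ``ramp_hours`` the linear transition after each set-point switch
    (default 12 h); ``phase_warm_first`` starts the profile at the beginning
    of a warm half cycle.
    """

    kind: Literal["constant", "fluctuating"]
    t_min: float
    t_max: float
    cycle_days: float = 14.0
    ramp_hours: float = 12.0
    n_cycles: int = 4
    dt_hours: float = 1.0
    phase_warm_first: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "fluctuating"):
            raise DesignError(f"unknown regime kind {self.kind!r}")
        if self.t_min > self.t_max:
            raise DesignError(f"t_min ({self.t_min}) > t_max ({self.t_max})")
        if self.kind == "constant" and self.t_min != self.t_max:
            raise DesignError("constant regime requires t_min == t_max")
        if not self.cycle_days > 0:
            raise DesignError("cycle_days must be > 0")
        if not (0 <= self.ramp_hours < self.cycle_days * 24.0 / 2.0):
            raise DesignError("ramp_hours must lie in [0, half-cycle)")
        if not self.dt_hours > 0:
            raise DesignError("dt_hours must be > 0")
        if not self.n_cycles >= 1:
            raise DesignError("n_cycles must be >= 1")

    @staticmethod
    def constant(temp: float, **kwargs) -> "RegimeSpec":
        return RegimeSpec(kind="constant", t_min=temp, t_max=temp, **kwargs)


#: The four amplitude treatments of the interaction experiment.
TREATMENT_REGIMES: dict[str, RegimeSpec] = {
    "constant": RegimeSpec.constant(23.0),
    "low": RegimeSpec(kind="fluctuating", t_min=22.0, t_max=24.0),
    "medium": RegimeSpec(kind="fluctuating", t_min=21.0, t_max=25.0),
    "high": RegimeSpec(kind="fluctuating", t_min=20.0, t_max=26.0),
}


def make_regime(spec: RegimeSpec) -> TemperatureProfile:
    """Generate the temperature profile described by ``spec``.

    The grid runs from 0 to ``n_cycles * cycle_days`` days inclusive with
    spacing ``dt_hours``.  For fluctuating specs the set point switches every
    half cycle, each switch followed by a linear ramp of ``ramp_hours``; the
    profile starts at the cold extreme ramping toward the warm set point
    (or the reverse with ``phase_warm_first=False``).
    """
    total_hours = spec.n_cycles * spec.cycle_days * 24.0
    n_steps = int(round(total_hours / spec.dt_hours))
    times = np.arange(n_steps + 1, dtype=float) * spec.dt_hours

    if spec.kind == "constant":
        return TemperatureProfile(times, np.full(times.shape, float(spec.t_min)))

    half = spec.cycle_days * 24.0 / 2.0
    hi, lo = (spec.t_max, spec.t_min)
    if not spec.phase_warm_first:
        hi, lo = lo, hi

    phase = np.mod(times, 2.0 * half)
    temps = np.empty_like(times)
    ramp = spec.ramp_hours
    # first half cycle: ramp lo -> hi, hold hi; second: ramp hi -> lo, hold lo
    in_first = phase < half
    p1 = phase
    p2 = phase - half
    if ramp > 0:
        up = lo + (hi - lo) * np.clip(p1 / ramp, 0.0, 1.0)
        down = hi + (lo - hi) * np.clip(p2 / ramp, 0.0, 1.0)
    else:
        up = np.full_like(times, hi)
        down = np.full_like(times, lo)
    temps = np.where(in_first, up, down)
    return TemperatureProfile(times, temps)


def regime_mean(profile: TemperatureProfile) -> float:
    """Trapezoid-rule time-average temperature of a profile (°C)."""
    if len(profile) < 2:
        raise DesignError("regime_mean needs at least 2 samples")
    return profile.mean_temp()


def write_profile(profile: TemperatureProfile, path) -> None:
    """Write a profile as two-column CSV (hours, temp_c)."""
    import pandas as pd

    pd.DataFrame({"hours": profile.times, "temp_c": profile.temps}).to_csv(
        path, index=False
    )


def read_profile(path) -> TemperatureProfile:
    """Read a two-column CSV profile (hours, temp_c), e.g. a logged bath trace."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    missing = {"hours", "temp_c"} - set(df.columns)
    if missing:
        raise DesignError(f"profile CSV missing columns: {sorted(missing)}")
    return TemperatureProfile(
        df["hours"].to_numpy(float), df["temp_c"].to_numpy(float)
    )
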