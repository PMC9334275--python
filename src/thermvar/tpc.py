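"""The O'Neill thermal performance curve and Jensen's-inequality machinery.

The O'Neill (1972) model describes a unimodal, left-skewed thermal
performance curve (TPC) with four parameters: the maximal rate ``rmax``
attained at the optimum temperature ``topt``, the upper critical limit
``ctmax`` at which performance falls to zero, and ``q10``, the fold change
in performance per 10 °C, which sets the steepness of the rising limb::

    rate(T) = rmax * ((ctmax - T) / (ctmax - topt))**x
                   * exp(x * (T - topt) / (ctmax - topt))

with the shape exponent ``x`` derived from ``w = (q10 - 1) * (ctmax - topt)``.
Two variants of the ``x`` formula circulate in the literature; see
:func:`oneill_aux` and ``docs/methods.md``.

Growth rates throughout the package are specific (log-scale) rates in
day⁻¹: ``(ln(final size) - ln(initial size)) / days``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Literal, Optional, Sequence

import numpy as np

from .errors import DomainError

XForm = Literal["canonical", "literal"]

__all__ = [
    "TPCParams",
    "GrowthObservation",
    "TemperatureProfile",
    "growth_rate",
    "oneill_aux",
    "oneill_rate",
    "secant_slope",
    "jensen_gap",
    "REFERENCE_TPC",
]


@dataclass(frozen=True)
class TPCParams:
    """The four O'Neill parameters.

    Parameters
    ----------
    rmax : float
        Maximal performance rate at ``topt`` (day⁻¹, specific growth rate).
    topt : float
        Optimum temperature (°C).
    ctmax : float
        Critical maximum temperature (°C) where the rate reaches zero;
        must exceed ``topt``.
    q10 : float
        Fold change in performance per 10 °C; must exceed 1 so the shape
        term ``w`` stays positive.
    """

    rmax: float
    topt: float
    ctmax: float
    q10: float

    def __post_init__(self) -> None:
        if not (self.rmax > 0):
            raise DomainError(f"rmax must be > 0, got {self.rmax}")
        if not (self.ctmax > self.topt):
            raise DomainError(
                f"ctmax ({self.ctmax}) must exceed topt ({self.topt})"
            )
        if not (self.q10 > 1):
            raise DomainError(f"q10 must be > 1, got {self.q10}")

    def replace(self, **kwargs) -> "TPCParams":
        return replace(self, **kwargs)


#: Point estimates for Enallagma cyathigerum larval growth used as the
#: package-wide reference parameter set in examples and simulations.
REFERENCE_TPC = TPCParams(rmax=0.0681, topt=26.9, ctmax=44.7, q10=2.56)


@dataclass
class GrowthObservation:
    """One larva's rearing temperature, sizes, duration and derived rate.

    ``rate`` stays ``None`` until computed; :func:`observed_rate` fills it
    from head widths via :func:`growth_rate`.
    """

    temp: float
    initial_hw: float
    final_hw: float
    duration: float
    rate: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("initial_hw", "final_hw", "duration"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if not math.isfinite(self.temp):
            raise DomainError(f"temp must be finite, got {self.temp}")

    def observed_rate(self) -> float:
        if self.rate is None:
            self.rate = growth_rate(self.initial_hw, self.final_hw, self.duration)
        return self.rate


@dataclass(frozen=True)
class TemperatureProfile:
    """A water-temperature time series on a strictly increasing hour grid."""

    times: np.ndarray  # hours since experiment start
    temps: np.ndarray  # °C

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)
        if times.ndim != 1 or times.shape != temps.shape:
            raise DomainError("times and temps must be 1-D arrays of equal length")
        if times.size == 0:
            raise DomainError("profile must be non-empty")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise DomainError("times must be strictly increasing")
        if not np.all(np.isfinite(temps)):
            raise DomainError("all temps must be finite")

    def __len__(self) -> int:
        return int(self.times.size)

    def mean_temp(self) -> float:
        """Trapezoid-rule time average of the temperature."""
        if len(self) < 2:
            return float(self.temps[0])
        span = self.times[-1] - self.times[0]
        return float(np.trapezoid(self.temps, self.times) / span)


def growth_rate(initial_hw: float, final_hw: float, duration: float) -> float:
    """Specific growth rate (day⁻¹) from initial and final head width (mm).

    Computed as ``(ln(final_hw) - ln(initial_hw)) / duration`` so the sign
    follows the sign of ``final_hw - initial_hw``.
    """
    if not initial_hw > 0:
        raise DomainError(f"initial_hw must be > 0, got {initial_hw}")
    if not final_hw > 0:
        raise DomainError(f"final_hw must be > 0, got {final_hw}")
    if not duration > 0:
        raise DomainError(f"duration must be > 0, got {duration}")
    return (math.log(final_hw) - math.log(initial_hw)) / duration


def oneill_aux(params: TPCParams, x_form: XForm = "canonical") -> tuple[float, float]:
    """Auxiliary O'Neill shape terms ``(w, x)``.

    ``w = (q10 - 1) * (ctmax - topt)`` and, in the canonical form,
    ``x = (w²/400) * (1 + sqrt(1 + 40/w))²``.  The ``literal`` variant places
    the square inside the radical, ``(w²/400) * (1 + sqrt((1 + 40/w)²))``,
    which collapses to ``(w²/400) * (2 + 40/w)`` for positive ``w``; it is
    retained only for comparison with that typeset variant.
    """
    w = (params.q10 - 1.0) * (params.ctmax - params.topt)
    if not w > 0:
        raise DomainError(
            f"w = (q10-1)(ctmax-topt) must be > 0, got {w}"
        )
    if x_form == "canonical":
        x = (w * w / 400.0) * (1.0 + math.sqrt(1.0 + 40.0 / w)) ** 2
    elif x_form == "literal":
        x = (w * w / 400.0) * (2.0 + 40.0 / w)
    else:
        raise DomainError(f"unknown x_form {x_form!r}")
    return w, x


def oneill_rate(
    params: TPCParams,
    temp,
    x_form: XForm = "canonical",
):
    """Evaluate the O'Neill TPC at ``temp`` (°C); vectorized over ``temp``.

    Returns ``rmax`` exactly at ``topt`` and exactly 0 for ``temp >= ctmax``
    (the model's base term turns negative there, and zero performance is the
    biologically meaningful continuation). There is no lower critical limit:
    rates decay smoothly toward zero with falling temperature.
    """
    _, x = oneill_aux(params, x_form)
    t = np.asarray(temp, dtype=float)
    if not np.all(np.isfinite(t)):
        raise DomainError("temp must be finite")
    span = params.ctmax - params.topt
    with np.errstate(invalid="ignore"):
        base = (params.ctmax - t) / span
        rate = np.where(
            base > 0,
            params.rmax * np.power(np.clip(base, 0, None), x)
            * np.exp(x * (t - params.topt) / span),
            0.0,
        )
    if np.isscalar(temp) or np.ndim(temp) == 0:
        return float(rate)
    return rate


def secant_slope(
    params: TPCParams, t1: float, t2: float, x_form: XForm = "canonical"
) -> float:
    """Chord slope of the TPC between two temperatures (day⁻¹ °C⁻¹).

    The slope of the secant through ``(t1, rate(t1))`` and ``(t2, rate(t2))``
    — the quantity compared between the 20–23 °C and 23–26 °C intervals to
    gauge local curvature around the fluctuation mean.
    """
    if t1 == t2:
        raise DomainError("t1 and t2 must differ")
    r1 = oneill_rate(params, t1, x_form)
    r2 = oneill_rate(params, t2, x_form)
    return (r2 - r1) / (t2 - t1)


def jensen_gap(
    params: TPCParams,
    profile: TemperatureProfile,
    x_form: XForm = "canonical",
    rate_fn: Optional[Callable] = None,
) -> float:
    """Jensen's-inequality gap of performance over a temperature profile.

    Returns the time average (trapezoid rule on the profile's own grid) of
    the performance rate minus the rate evaluated at the time-mean
    temperature.  Zero for constant profiles and for affine performance
    functions; negative where the TPC is concave over the excursion range,
    as expected just below the optimum.

    ``rate_fn(temps) -> rates`` overrides the O'Neill evaluator (test hook
    for the affine-equality property).
    """
    if len(profile) < 2:
        raise DomainError("profile must contain at least 2 samples for the gap")
    if rate_fn is None:
        rate_fn = lambda t: oneill_rate(params, t, x_form)  # noqa: E731
    if np.all(profile.temps == profile.temps[0]):
        return 0.0  # no variance, so the gap is identically zero
    rates = np.asarray(rate_fn(profile.temps), dtype=float)
    span = profile.times[-1] - profile.times[0]
    mean_rate = float(np.trapezoid(rates, profile.times) / span)
    rate_at_mean = float(np.asarray(rate_fn(profile.mean_temp()), dtype=float))
    return mean_rate - rate_at_mean
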