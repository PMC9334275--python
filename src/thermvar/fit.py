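"""Nonlinear least-squares estimation of O'Neill TPC parameters.

Growth observations (one rate per larva per rearing temperature) are fit by
bounded trust-region least squares (:func:`scipy.optimize.least_squares`)
with data-driven start values and seeded multi-start jitter to escape the
local minima typical of peaked TPCs.  Case-resampling bootstrap intervals
are available via :func:`bootstrap_ci`.

A caveat inherent to the experimental design: with all rearing temperatures
left of the optimum (17–28 °C against a ~27 °C optimum), ``ctmax`` is only
weakly identified at realistic noise; expect wide intervals for it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DesignError, DomainError
from .tpc import GrowthObservation, TPCParams, XForm, oneill_rate

__all__ = [
    "FitResult",
    "fit_oneill",
    "default_starts",
    "bootstrap_ci",
    "read_observations",
    "write_fit_result",
]

_N_RESTARTS = 10
_JITTER = 0.20  # relative multi-start perturbation


@dataclass
class FitResult:
    """Point estimates plus fit diagnostics and optional bootstrap CIs."""

    params: TPCParams
    rss: float
    converged: bool
    n_iter: int
    starts: TPCParams
    ci: Optional[dict] = None

    def to_dict(self) -> dict:
        d = {
            "rmax": self.params.rmax,
            "topt": self.params.topt,
            "ctmax": self.params.ctmax,
            "q10": self.params.q10,
            "rss": self.rss,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        d["ci"] = self.ci
        return d


def _extract(observations: Sequence[GrowthObservation]) -> tuple[np.ndarray, np.ndarray]:
    temps = np.array([o.temp for o in observations], dtype=float)
    rates = np.array([o.observed_rate() for o in observations], dtype=float)
    return temps, rates


def default_starts(observations: Sequence[GrowthObservation]) -> TPCParams:
    """Heuristic start values from the observed rate-by-temperature means.

    The start optimum is the temperature with the highest mean observed rate
    (lowest such temperature on ties), the start ``rmax`` that mean rate,
    ``ctmax`` the warmest rearing temperature plus 15 °C, and ``q10`` 2.
    """
    if len(observations) == 0:
        raise DesignError("no observations")
    temps, rates = _extract(observations)
    uniq = np.unique(temps)
    if uniq.size < 2:
        raise DesignError("need at least 2 distinct temperatures for start values")
    means = np.array([rates[temps == t].mean() for t in uniq])
    best = int(np.argmax(means))  # argmax takes the first (lowest) on ties
    rmax0 = float(means[best])
    if rmax0 <= 0:
        rmax0 = max(float(np.max(np.abs(rates))), 1e-6)
    return TPCParams(
        rmax=rmax0,
        topt=float(uniq[best]),
        ctmax=float(uniq.max()) + 15.0,
        q10=2.0,
    )


def _default_bounds(temps: np.ndarray, rates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rmax_hi = 10.0 * max(float(np.max(np.abs(rates))), 1e-9)
    lo = np.array([1e-12, float(temps.min()), float(temps.min()) + 1e-6, 1.0 + 1e-9])
    hi = np.array([rmax_hi, float(temps.max()) + 20.0, float(temps.max()) + 40.0, 10.0])
    return lo, hi


def fit_oneill(
    observations: Sequence[GrowthObservation],
    starts: Optional[TPCParams] = None,
    bounds: Optional[tuple[Sequence[float], Sequence[float]]] = None,
    seed: int = 0,
    n_restarts: int = _N_RESTARTS,
    x_form: XForm = "canonical",
) -> FitResult:
    """Fit the O'Neill TPC to growth observations by least squares.

    Minimizes the sum of squared rate residuals over (rmax, topt, ctmax,
    q10) within bounds, restarting ``n_restarts`` times from seeded ±20%
    jitters of the start values and keeping the best residual sum of
    squares.  Non-convergence on every restart is reported via
    ``converged=False`` rather than an exception.
    """
    temps, rates = _extract(observations)
    if np.unique(temps).size < 4:
        raise DesignError(
            "need >= 4 distinct temperatures to identify the four parameters"
        )
    if starts is None:
        starts = default_starts(observations)
    if bounds is None:
        lo, hi = _default_bounds(temps, rates)
    else:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)

    def residuals(theta: np.ndarray) -> np.ndarray:
        rmax, topt, ctmax, q10 = theta
        if not (ctmax > topt and q10 > 1 and rmax > 0):
            return np.full_like(rates, 1e6)
        p = TPCParams(rmax=rmax, topt=topt, ctmax=ctmax, q10=q10)
        return rates - oneill_rate(p, temps, x_form)

    theta0 = np.array([starts.rmax, starts.topt, starts.ctmax, starts.q10])
    theta0 = np.clip(theta0, lo, hi)
    rng = np.random.default_rng(seed)

    best = None
    n_iter_total = 0
    any_converged = False
    for k in range(max(1, n_restarts)):
        if k == 0:
            t0 = theta0
        else:
            t0 = np.clip(theta0 * (1.0 + rng.uniform(-_JITTER, _JITTER, 4)), lo, hi)
        try:
            sol = least_squares(
                residuals, t0, bounds=(lo, hi), method="trf",
                ftol=1e-10, xtol=1e-8, gtol=1e-12,
            )
        except Exception:
            continue
        n_iter_total += int(sol.nfev)
        rss = float(2.0 * sol.cost)
        if sol.success:
            any_converged = True
        if best is None or rss < best[0]:
            best = (rss, sol.x, bool(sol.success))

    if best is None:
        return FitResult(params=starts, rss=float(np.sum(residuals(theta0) ** 2)),
                         converged=False, n_iter=n_iter_total, starts=starts)
    rss, x, ok = best
    rmax, topt, ctmax, q10 = (float(v) for v in x)
    # guard the invariants against bound-edge round-off
    ctmax = max(ctmax, topt + 1e-9)
    q10 = max(q10, 1.0 + 1e-12)
    rmax = max(rmax, 1e-15)
    params = TPCParams(rmax=rmax, topt=topt, ctmax=ctmax, q10=q10)
    return FitResult(params=params, rss=rss, converged=any_converged and ok,
                     n_iter=n_iter_total, starts=starts)


def bootstrap_ci(
    observations: Sequence[GrowthObservation],
    n_boot: int = 200,
    level: float = 0.95,
    seed: int = 0,
    n_restarts: int = 3,
    x_form: XForm = "canonical",
) -> dict:
    """Case-resampling bootstrap percentile intervals for the parameters.

    Observations are resampled with replacement and refit ``n_boot`` times;
    resamples with fewer than 4 distinct temperatures are redrawn.  Returns
    ``{param: (lower, upper)}`` plus the confidence ``level``.
    """
    if n_boot < 2:
        raise DesignError("n_boot must be >= 2")
    base = fit_oneill(observations, seed=seed, n_restarts=n_restarts, x_form=x_form)
    rng = np.random.default_rng(seed)
    obs = list(observations)
    n = len(obs)
    draws = {k: [] for k in ("rmax", "topt", "ctmax", "q10")}
    b = 0
    attempts = 0
    while b < n_boot and attempts < 20 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, n)
        sample = [obs[i] for i in idx]
        if np.unique([o.temp for o in sample]).size < 4:
            continue
        res = fit_oneill(
            sample, starts=base.params, seed=int(rng.integers(0, 2**31 - 1)),
            n_restarts=n_restarts, x_form=x_form,
        )
        draws["rmax"].append(res.params.rmax)
        draws["topt"].append(res.params.topt)
        draws["ctmax"].append(res.params.ctmax)
        draws["q10"].append(res.params.q10)
        b += 1
    alpha = (1.0 - level) / 2.0
    ci = {
        k: (float(np.quantile(v, alpha)), float(np.quantile(v, 1.0 - alpha)))
        for k, v in draws.items()
    }
    ci["level"] = level
    return ci


def read_observations(path: str | Path) -> list[GrowthObservation]:
    """Read growth observations from CSV with columns
    temp_c, initial_hw_mm, final_hw_mm, duration_days."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    required = {"temp_c", "initial_hw_mm", "final_hw_mm", "duration_days"}
    missing = required - set(df.columns)
    if missing:
        raise DesignError(f"observations CSV missing columns: {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                GrowthObservation(
                    temp=float(row["temp_c"]),
                    initial_hw=float(row["initial_hw_mm"]),
                    final_hw=float(row["final_hw_mm"]),
                    duration=float(row["duration_days"]),
                )
            )
        except (DomainError, ValueError) as e:
            raise DesignError(f"bad observation at data row {i}: {e}") from e
    return out


def write_fit_result(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")
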