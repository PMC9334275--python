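"""Individual-based synthetic-data generator for the larval experiments.

Two generators:

* :func:`simulate_single_growth` emulates the thermal-performance design —
  singly reared larvae at a set of constant temperatures, each larva's
  realized specific growth rate drawn as the TPC rate plus Gaussian noise.

* :func:`simulate_cohort` emulates one treatment arm of the interaction
  experiment: containers of larvae growing under a temperature regime, with
  size-dependent cannibalism (a random encounter is lethal only when the
  larger larva's head width exceeds the smaller's by a threshold ratio),
  a small intrinsic (non-cannibalism) death hazard, and weekly censuses.
  Cannibalized larvae vanish without trace — they are the "missing larvae"
  cannibalism proxy — whereas intrinsic deaths leave carcasses discovered at
  the next census.

Every stochastic choice flows from the config seed, so identical configs
give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import SYNTHETIC_COHORT_DEFAULTS as _CAL
from .errors import DesignError, DomainError
from .tpc import GrowthObservation, TemperatureProfile, TPCParams, oneill_rate

__all__ = [
    "Larva",
    "CohortConfig",
    "simulate_cohort",
    "simulate_single_growth",
    "simulate_interaction_experiment",
    "write_simulation_outputs",
]


@dataclass
class Larva:
    """One simulated individual and its fate."""

    id: str
    head_width: float
    fate: str = "alive"  # alive | cannibalized | intrinsic_death
    fate_day: Optional[int] = None


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one interaction-experiment treatment arm.

    Design fields (counts, duration) mirror the experiment: 10 larvae per
    container, 10 containers, eight weeks.  Mechanism fields (rates, noise,
    the size-ratio threshold) are synthetic calibration constants; see
    :mod:`thermvar.calibration`.
    """

    n_per_container: int = _CAL["n_per_container"]
    n_containers: int = _CAL["n_containers"]
    duration_days: int = _CAL["duration_days"]
    init_hw_mean: float = _CAL["init_hw_mean"]
    init_hw_cv: float = _CAL["init_hw_cv"]
    growth_noise_sd: float = _CAL["growth_noise_sd"]
    intrinsic_hazard: float = _CAL["intrinsic_hazard"]
    encounter_rate_ref: float = _CAL["encounter_rate_ref"]
    activity_q10: float = _CAL["activity_q10"]
    size_ratio_threshold: float = _CAL["size_ratio_threshold"]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_container < 1 or self.n_containers < 1:
            raise DesignError("counts must be >= 1")
        if self.duration_days < 1:
            raise DesignError("duration_days must be >= 1")
        if not (self.init_hw_mean > 0 and self.init_hw_cv >= 0):
            raise DesignError("initial size parameters out of range")
        if self.growth_noise_sd < 0:
            raise DesignError("growth_noise_sd must be >= 0")
        if not (0.0 <= self.intrinsic_hazard <= 1.0):
            raise DesignError("intrinsic_hazard must be a probability")
        if self.encounter_rate_ref < 0:
            raise DesignError("encounter_rate_ref must be >= 0")
        if self.activity_q10 <= 0:
            raise DesignError("activity_q10 must be > 0")
        if not self.size_ratio_threshold >= 1.0:
            raise DesignError("size_ratio_threshold must be >= 1")


def _initial_sizes(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    """Lognormal sizes with the given arithmetic mean and CV (positive by construction)."""
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def _noon_temps(regime: TemperatureProfile, duration_days: int) -> np.ndarray:
    """Regime temperature at noon of each experiment day (day 1..duration)."""
    noon = (np.arange(duration_days) * 24.0) + 12.0
    if regime.times[-1] < (duration_days * 24.0) - 12.0:
        raise DesignError(
            f"regime covers {regime.times[-1] / 24.0:.1f} days, "
            f"needs {duration_days}"
        )
    return np.interp(noon, regime.times, regime.temps)


def simulate_cohort(
    config: CohortConfig,
    regime: TemperatureProfile,
    tpc: TPCParams,
    treatment: str = "treatment",
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Simulate one treatment arm; returns (census, measurements, events).

    Daily, per container: every live larva grows by
    ``hw <- hw * exp(oneill_rate(tpc, T_day) + eps)`` with
    ``eps ~ N(0, growth_noise_sd)``; each live larva dies intrinsically with
    probability ``intrinsic_hazard``; the number of pairwise encounters is
    Poisson with mean ``encounter_rate_ref * activity_q10**((T-23)/10) *
    n(n-1)/90`` (so a full container of 10 at 23 °C sees the reference
    rate), pairs drawn uniformly without replacement; an encounter kills the
    smaller larva iff larger/smaller head width >= the threshold ratio.

    Census rows cover week 0 (initial count) through the final week; the
    carcass column counts intrinsic deaths discovered since the previous
    census.  Cannibalized larvae leave no carcass.
    """
    temps = _noon_temps(regime, config.duration_days)
    rng = np.random.default_rng(config.seed)
    rho = config.size_ratio_threshold

    census_rows: list[dict] = []
    meas_rows: list[dict] = []
    events: list[dict] = []

    n_weeks = config.duration_days // 7

    for c in range(config.n_containers):
        larvae = [
            Larva(id=f"{treatment}-c{c:02d}-l{i:02d}", head_width=float(h))
            for i, h in enumerate(
                _initial_sizes(rng, config.n_per_container,
                               config.init_hw_mean, config.init_hw_cv)
            )
        ]
        for lv in larvae:
            meas_rows.append({
                "treatment": treatment, "container": c, "larva_id": lv.id,
                "phase": "start", "head_width_mm": lv.head_width,
            })
        census_rows.append({
            "treatment": treatment, "container": c, "week": 0,
            "n_alive": len(larvae), "n_carcasses": 0,
        })

        undiscovered = 0  # intrinsic carcasses since last census
        for day in range(1, config.duration_days + 1):
            t_day = temps[day - 1]
            alive = [lv for lv in larvae if lv.fate == "alive"]
            if alive:
                base = oneill_rate(tpc, float(t_day))
                eps = rng.normal(0.0, config.growth_noise_sd, len(alive))
                for lv, e in zip(alive, eps):
                    lv.head_width *= math.exp(base + e)
                # intrinsic mortality
                dies = rng.random(len(alive)) < config.intrinsic_hazard
                for lv, d in zip(alive, dies):
                    if d:
                        lv.fate = "intrinsic_death"
                        lv.fate_day = day
                        undiscovered += 1
                        events.append({
                            "day": day, "container": c, "type": "intrinsic",
                            "cannibal_id": None, "victim_id": lv.id,
                        })
            alive = [lv for lv in larvae if lv.fate == "alive"]
            n = len(alive)
            if n >= 2 and config.encounter_rate_ref > 0 and np.isfinite(rho):
                mean_enc = (
                    config.encounter_rate_ref
                    * config.activity_q10 ** ((t_day - 23.0) / 10.0)
                    * n * (n - 1) / 90.0
                )
                n_enc = int(rng.poisson(mean_enc))
                n_pairs = n * (n - 1) // 2
                n_enc = min(n_enc, n_pairs)
                if n_enc > 0:
                    pair_idx = rng.choice(n_pairs, size=n_enc, replace=False)
                    pairs = [_unrank_pair(int(k), n) for k in pair_idx]
                    for i, j in pairs:
                        a, b = alive[i], alive[j]
                        if a.fate != "alive" or b.fate != "alive":
                            continue
                        big, small = (a, b) if a.head_width >= b.head_width else (b, a)
                        if small.head_width > 0 and big.head_width / small.head_width >= rho:
                            small.fate = "cannibalized"
                            small.fate_day = day
                            events.append({
                                "day": day, "container": c, "type": "cannibalism",
                                "cannibal_id": big.id, "victim_id": small.id,
                                "cannibal_hw": big.head_width,
                                "victim_hw": small.head_width,
                            })
            if day % 7 == 0:
                census_rows.append({
                    "treatment": treatment, "container": c, "week": day // 7,
                    "n_alive": sum(lv.fate == "alive" for lv in larvae),
                    "n_carcasses": undiscovered,
                })
                undiscovered = 0

        for lv in larvae:
            if lv.fate == "alive":
                meas_rows.append({
                    "treatment": treatment, "container": c, "larva_id": lv.id,
                    "phase": "end", "head_width_mm": lv.head_width,
                })

    census = pd.DataFrame(census_rows)
    measurements = pd.DataFrame(meas_rows)
    return census, measurements, events


def _unrank_pair(k: int, n: int) -> tuple[int, int]:
    """Map rank k in [0, C(n,2)) to the k-th lexicographic (i, j), i < j."""
    i = 0
    remaining = k
    row = n - 1
    while remaining >= row:
        remaining -= row
        i += 1
        row -= 1
    return i, i + 1 + remaining


def simulate_single_growth(
    n_per_temp: int,
    temps: Sequence[float],
    tpc: TPCParams,
    noise_sd: float,
    duration_days: float = 63.0,
    init_hw: float = 1.2,
    seed: int = 0,
) -> list[GrowthObservation]:
    """Singly reared larvae at constant temperatures (TPC-experiment design).

    Each observation's realized rate is ``oneill_rate(tpc, temp) +
    N(0, noise_sd)``; the final head width is back-computed so that the
    growth-rate formula reproduces the realized rate exactly.
    """
    if len(temps) == 0:
        raise DesignError("temps must be non-empty")
    if noise_sd < 0:
        raise DesignError("noise_sd must be >= 0")
    if n_per_temp < 1:
        raise DesignError("n_per_temp must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[GrowthObservation] = []
    for t in temps:
        base = oneill_rate(tpc, float(t))
        noise = rng.normal(0.0, noise_sd, n_per_temp) if noise_sd > 0 else np.zeros(n_per_temp)
        for e in noise:
            rate = base + float(e)
            final = init_hw * math.exp(rate * duration_days)
            out.append(GrowthObservation(
                temp=float(t), initial_hw=init_hw, final_hw=final,
                duration=duration_days,
            ))
    return out


def simulate_interaction_experiment(
    tpc: TPCParams,
    config: Optional[CohortConfig] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Run all four amplitude treatments and concatenate their outputs.

    Treatments (constant 23, low 22–24, medium 21–25, high 20–26 °C) share
    the config except for the temperature regime; per-treatment seeds are
    derived from ``seed``.
    """
    from dataclasses import replace

    from .regimes import TREATMENT_REGIMES, make_regime

    if config is None:
        config = CohortConfig(seed=seed)
    censuses, measures, events = [], [], []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(TREATMENT_REGIMES))
    for (name, spec), child in zip(TREATMENT_REGIMES.items(), children):
        arm_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        arm_cfg = replace(config, seed=arm_seed)
        regime = make_regime(spec)
        cen, mea, ev = simulate_cohort(arm_cfg, regime, tpc, treatment=name)
        censuses.append(cen)
        measures.append(mea)
        events.extend(ev)
    return (
        pd.concat(censuses, ignore_index=True),
        pd.concat(measures, ignore_index=True),
        events,
    )


def write_simulation_outputs(
    outdir: str | Path,
    census: pd.DataFrame,
    measurements: pd.DataFrame,
    events: list[dict],
    manifest: Optional[dict] = None,
) -> None:
    """Write census.csv, measurements.csv, events.jsonl and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    census.to_csv(outdir / "census.csv", index=False)
    measurements.to_csv(outdir / "measurements.csv", index=False)
    with open(outdir / "events.jsonl", "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev) + "\n")
    if manifest is not None:
        (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
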