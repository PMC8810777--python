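"""Replicated parameter sweeps with standard-error aggregation.

Every replicate has its own stored seed so any single run is reproducible
in isolation; aggregates (mean, standard error = sample standard deviation
over sqrt(n), censored count) recompute exactly from the per-replicate rows.
Censored extinction times enter the mean at the censoring value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import run_simulation
from .model_core import SimulationConfig, validate_config
from .observables import extinction_time, interface_width, summarize

__all__ = [
    "SweepSpec",
    "SweepResult",
    "aggregate_replicates",
    "sweep_extinction_vs_k",
    "sweep_traditional_vs_territorial",
    "sweep_width_vs_k",
    "phase_scan_mobility",
    "transition_midpoint",
    "trend_pvalue",
    "make_seeds",
]

MEASUREMENTS = (
    "extinction_time_low",
    "extinction_time_high",
    "width_at_t",
    "phase_state",
)


@dataclass(frozen=True)
class SweepSpec:
    """One replicated sweep over ``k`` or ``M``.

    Seeds are either given explicitly (``seeds``, one per
    ``(value, replicate)`` in row-major order) or derived from
    ``base_seed`` via a seed sequence; they must all be distinct.
    """

    base: SimulationConfig
    sweep_variable: str  # "k" | "M"
    values: tuple
    replicates: int
    measurement: str
    base_seed: int = 0
    seeds: Optional[tuple] = None
    t_measure: Optional[int] = None  # generation at which width is measured
    censor_at: Optional[int] = None  # extinction censoring horizon


@dataclass
class SweepResult:
    """Per-replicate rows plus their exact aggregates."""

    spec: SweepSpec
    replicates: pd.DataFrame  # value, replicate, seed, measurement, censored
    aggregates: pd.DataFrame  # value, mean, standard_error, n, n_censored


def make_seeds(spec: SweepSpec) -> np.ndarray:
    """Distinct seeds, one per (value, replicate), row-major."""
    n = len(spec.values) * spec.replicates
    if spec.seeds is not None:
        seeds = np.asarray(spec.seeds, dtype=np.int64)
        if seeds.shape != (n,):
            raise ValueError(f"need {n} seeds, got {seeds.shape}")
    else:
        seeds = np.random.SeedSequence(spec.base_seed).generate_state(n, np.uint64)
        seeds = (seeds >> np.uint64(1)).astype(np.int64)  # keep in int64 range
    if len(set(seeds.tolist())) != n:
        raise ValueError("replicate seeds must be distinct")
    return seeds


def _validate_spec(spec: SweepSpec) -> None:
    validate_config(spec.base)
    if spec.sweep_variable not in ("k", "M"):
        raise ValueError(f"unknown sweep variable {spec.sweep_variable!r}")
    if spec.replicates < 1:
        raise ValueError("replicates must be >= 1")
    if spec.measurement not in MEASUREMENTS:
        raise ValueError(f"unknown measurement {spec.measurement!r}")


def _apply_value(config: SimulationConfig, variable: str, value) -> SimulationConfig:
    if variable == "k":
        return config.with_k(float(value))
    return replace(config, M=float(value))


def aggregate_replicates(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean/SE/censored-count per swept value, straight from the rows.

    SE is the sample standard deviation divided by sqrt(n); with a single
    replicate it is reported as 0 (and n = 1 flags the degeneracy).
    """
    out = []
    for value, grp in rows.groupby("value", sort=True):
        x = grp["measurement"].to_numpy(dtype=float)
        n = len(x)
        se = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(
            {
                "value": value,
                "mean": float(np.mean(x)),
                "standard_error": se,
                "n": n,
                "n_censored": int(grp["censored"].sum()),
            }
        )
    return pd.DataFrame(out)


def _measure_extinction(config, seed, definition, censor_at):
    censor = censor_at if censor_at is not None else config.T_max
    cfg = replace(config, seed=int(seed), T_max=int(censor), record_every=1)
    stop = "genus_extinct" if definition == "low_mobility" else "two_species_extinct"
    run = run_simulation(cfg, stop_mode=stop)
    rec = extinction_time(run.densities, definition, censor_at=censor)
    return rec.time, rec.status == "censored"


def _measure_width(config, seed, t_measure):
    cfg = replace(
        config,
        seed=int(seed),
        T_max=int(t_measure),
        record_every=max(1, int(t_measure)),
    )
    run = run_simulation(cfg)
    return interface_width(run.final_state).W, False


def _measure_phase(config, seed, t_end):
    cfg = replace(config, seed=int(seed), T_max=int(t_end),
                  record_every=max(1, int(t_end)))
    run = run_simulation(cfg)
    coexists = len(summarize(run.final_state).species_alive) == 3
    return float(coexists), False


def _run_sweep(spec: SweepSpec, config_for_value, measure) -> SweepResult:
    seeds = make_seeds(spec)
    rows = []
    i = 0
    for value in spec.values:
        cfg = config_for_value(value)
        for rep in range(spec.replicates):
            seed = int(seeds[i])
            i += 1
            measurement, censored = measure(cfg, seed)
            rows.append(
                {
                    "value": float(value),
                    "replicate": rep,
                    "seed": seed,
                    "measurement": measurement,
                    "censored": bool(censored),
                }
            )
    df = pd.DataFrame(rows)
    return SweepResult(spec=spec, replicates=df, aggregates=aggregate_replicates(df))


def sweep_extinction_vs_k(spec: SweepSpec) -> SweepResult:
    """Mean extinction time vs sensitivity k at fixed mobility.

    The extinction definition must be chosen explicitly through
    ``spec.measurement`` (``extinction_time_low`` for the low-mobility
    genus-loss definition, ``extinction_time_high`` for two-species loss);
    it is never inferred from M.
    """
    _validate_spec(spec)
    if spec.sweep_variable != "k":
        raise ValueError("sweep_extinction_vs_k sweeps k")
    if spec.measurement not in ("extinction_time_low", "extinction_time_high"):
        raise ValueError("measurement must be an extinction time")
    definition = (
        "low_mobility" if spec.measurement == "extinction_time_low" else "high_mobility"
    )
    return _run_sweep(
        spec,
        lambda v: _apply_value(spec.base, "k", v),
        lambda cfg, seed: _measure_extinction(cfg, seed, definition, spec.censor_at),
    )


def sweep_traditional_vs_territorial(spec: SweepSpec):
    """Matched-seed extinction sweep in both intraspecific modes.

    Returns ``(territorial, traditional)`` results; replicate ``i`` of every
    k value uses the same seed in both modes.
    """
    _validate_spec(spec)
    seeds = tuple(make_seeds(spec).tolist())
    results = []
    for mode in ("territorial", "traditional"):
        mode_spec = replace(
            spec, base=replace(spec.base, intraspecific_mode=mode), seeds=seeds
        )
        results.append(sweep_extinction_vs_k(mode_spec))
    return tuple(results)


def sweep_width_vs_k(spec: SweepSpec) -> SweepResult:
    """Mean interface width at generation ``t_measure`` vs k."""
    _validate_spec(spec)
    if spec.measurement != "width_at_t":
        raise ValueError("measurement must be width_at_t")
    t = spec.t_measure if spec.t_measure is not None else 1000
    return _run_sweep(
        spec,
        lambda v: _apply_value(spec.base, spec.sweep_variable, v),
        lambda cfg, seed: _measure_width(cfg, seed, t),
    )


def phase_scan_mobility(spec: SweepSpec) -> SweepResult:
    """Coexistence probability vs mobility at T = N generations.

    Each replicate scores 1 when all three species are alive at the end of
    the run (T = N generations unless ``t_measure`` overrides it); the
    aggregate mean is the coexistence probability.
    """
    _validate_spec(spec)
    if spec.sweep_variable != "M":
        raise ValueError("phase_scan_mobility sweeps M")
    if spec.measurement != "phase_state":
        raise ValueError("measurement must be phase_state")
    t_end = spec.t_measure if spec.t_measure is not None else spec.base.N
    return _run_sweep(
        spec,
        lambda v: _apply_value(spec.base, "M", v),
        lambda cfg, seed: _measure_phase(cfg, seed, t_end),
    )


def transition_midpoint(aggregates: pd.DataFrame) -> Optional[float]:
    """Mobility at which the coexistence probability crosses 1/2.

    Log-linear interpolation between the last grid point with probability
    >= 1/2 and the first later point below 1/2, after sorting by M.  Returns
    None when the scan does not bracket the crossing or holds a single
    point.
    """
    df = aggregates.sort_values("value")
    M = df["value"].to_numpy(dtype=float)
    p = df["mean"].to_numpy(dtype=float)
    if len(M) < 2:
        return None
    for i in range(len(M) - 1):
        if p[i] >= 0.5 > p[i + 1]:
            x0, x1 = np.log10(M[i]), np.log10(M[i + 1])
            if p[i] == p[i + 1]:
                return float(10 ** ((x0 + x1) / 2))
            f = (p[i] - 0.5) / (p[i] - p[i + 1])
            return float(10 ** (x0 + f * (x1 - x0)))
    return None


def trend_pvalue(
    values: Sequence[float],
    measurements: Sequence[float],
    alternative: str = "greater",
) -> float:
    """One-sided Spearman trend test on per-replicate (value, measurement).

    ``alternative='greater'`` tests for an increasing trend.  Constant
    inputs return p = 1 (no evidence of trend).
    """
    values = np.asarray(values, dtype=float)
    measurements = np.asarray(measurements, dtype=float)
    if np.all(values == values[0]) or np.all(measurements == measurements[0]):
        return 1.0
    res = stats.spearmanr(values, measurements, alternative=alternative)
    return float(res.pvalue)
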