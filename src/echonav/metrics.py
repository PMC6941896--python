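"""Performance measures: collision rates, reductions, corridor outcomes,
and the summary statistics reported alongside them.

Collision rates pool totals across trials (total collisions divided by
total simulated time or total path length), matching a rate interpretation
rather than a mean of per-trial rates; per-trial bootstrap confidence
intervals are available separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .environments import Environment
from .simulator import TrialResult

__all__ = [
    "collision_rates",
    "reduction_pct",
    "corridor_outcomes",
    "CorridorOutcome",
    "chi2_proportions_yates",
    "trajectory_summaries",
    "pooled_values",
    "bootstrap_rate_ci",
]


def collision_rates(results: Sequence[TrialResult]) -> tuple[float, float]:
    """Pooled (collisions per second, collisions per metre) over all trials."""
    if not results:
        raise ValueError("results must be non-empty")
    n_coll = sum(len(r.collisions) for r in results)
    duration = sum(r.duration for r in results)
    path = sum(r.path_length for r in results)
    if duration <= 0 or path <= 0:
        raise ZeroDivisionError("total duration and path length must be positive")
    return n_coll / duration, n_coll / path


def reduction_pct(baseline_rate: float, rate: float) -> float:
    """Percent reduction of ``rate`` relative to ``baseline_rate``: 100 (1 - rate/baseline)."""
    if baseline_rate <= 0:
        raise ZeroDivisionError("baseline rate must be > 0")
    return 100.0 * (1.0 - rate / baseline_rate)


@dataclass(frozen=True)
class CorridorOutcome:
    n_trials: int
    n_completed: int
    proportion: float
    ci_low: float
    ci_high: float


def corridor_outcomes(results: Sequence[TrialResult]) -> CorridorOutcome:
    """Success proportion (termination == completed) with a Wilson 95% CI."""
    if not results:
        raise ValueError("results must be non-empty")
    n = len(results)
    k = sum(r.termination == "completed" for r in results)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return CorridorOutcome(
        n_trials=n, n_completed=k, proportion=k / n, ci_low=float(lo), ci_high=float(hi)
    )


def chi2_proportions_yates(table: Sequence[Sequence[float]]) -> float:
    """Yates continuity-corrected chi-square statistic for a 2x2 table.

    N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)), with the continuity
    correction clamped at zero when |ad - bc| < N/2.
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ZeroDivisionError("all table marginals must be > 0")
    num = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    return float(num / margins)


def pooled_values(results: Sequence[TrialResult], env: Environment | None = None) -> pd.DataFrame:
    """Pool per-call values across trials into one long table.

    Columns: speed (m/s), body_rate (|delta_theta|/ipi, deg/s), d_hat (m,
    NaN when undetected), true_nearest (m), and axis_angle (deg, absolute
    heading relative to the corridor axis) when ``env`` is a corridor.
    """
    frames = []
    for r in results:
        ipi = r.duration / r.n_calls_executed if r.n_calls_executed else np.nan
        d = {
            "speed": r.speed,
            "body_rate": np.abs(r.delta_theta) / ipi,
            "d_hat": r.d_hat,
            "true_nearest": r.true_nearest,
        }
        if env is not None and env.kind == "corridor":
            axis_deg = np.degrees(np.arctan2(env.corridor_axis[1], env.corridor_axis[0]))
            d["axis_angle"] = np.abs((r.theta - axis_deg + 180.0) % 360.0 - 180.0)
        frames.append(pd.DataFrame(d))
    return pd.concat(frames, ignore_index=True)


def _summary(series: pd.Series) -> dict[str, float]:
    v = series.dropna().to_numpy()
    if len(v) == 0:
        return {"median": np.nan, "iqr": np.nan, "variance": np.nan}
    q1, q3 = np.percentile(v, [25, 75])
    return {"median": float(np.median(v)), "iqr": float(q3 - q1), "variance": float(np.var(v))}


def trajectory_summaries(
    results_by_strategy: Mapping[str, Sequence[TrialResult]],
    env: Environment | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strategy medians/dispersions plus cross-strategy test statistics.

    Returns ``(summary, tests)``: ``summary`` has one row per (strategy,
    variable) with median, IQR and variance of the pooled per-call values;
    ``tests`` has, per variable, the Kruskal-Wallis H statistic (rank-based
    location) and the Levene W statistic (variance homogeneity) across
    strategies, for reporting parity with the robot experiments.
    """
    pools = {name: pooled_values(res, env) for name, res in results_by_strategy.items()}
    rows = []
    for name, df in pools.items():
        for var in df.columns:
            rows.append({"strategy": name, "variable": var, **_summary(df[var])})
    summary = pd.DataFrame(rows)

    tests = []
    if len(pools) >= 2:
        variables = set.intersection(*(set(df.columns) for df in pools.values()))
        for var in sorted(variables):
            groups = [df[var].dropna().to_numpy() for df in pools.values()]
            if any(len(g) < 2 for g in groups):
                continue
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):  # degenerate: every value tied
                continue
            h, p_h = stats.kruskal(*groups)
            w, p_w = stats.levene(*groups, center="median")
            tests.append(
                {
                    "variable": var,
                    "kruskal_h": float(h),
                    "kruskal_p": float(p_h),
                    "levene_w": float(w),
                    "levene_p": float(p_w),
                }
            )
    return summary, pd.DataFrame(tests)


def bootstrap_rate_ci(
    results: Sequence[TrialResult],
    which: str = "per_meter",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI (resampling trials) on a pooled collision rate."""
    if which not in ("per_second", "per_meter"):
        raise ValueError("which must be 'per_second' or 'per_meter'")
    rng = np.random.default_rng(seed)
    coll = np.array([len(r.collisions) for r in results], dtype=float)
    denom = np.array(
        [r.duration if which == "per_second" else r.path_length for r in results], dtype=float
    )
    idx = rng.integers(0, len(results), size=(n_boot, len(results)))
    rates = coll[idx].sum(axis=1) / denom[idx].sum(axis=1)
    lo, hi = np.percentile(rates, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
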