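"""Fe(II) production kinetics estimated from culture time series.

The exponential phase is operationalised as the contiguous window of
timepoints maximising the R^2 of a straight-line fit of log10(cell density)
against time (the growth-curve criterion; the window is selectable by hand
where a fixed window is preferred).  The Fe(II) production rate is then the
ordinary least-squares slope of total Fe(II) against time inside that window,
in mM/day.  Stationary-phase accumulation is the mean of the last few
observations, and soluble/sediment partitioning follows the assay convention
sediment = total - soluble.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .culture import CultureSeries, TOLERANCE_MM

__all__ = [
    "RateEstimate",
    "select_exponential_window",
    "fe2_production_rate",
    "final_accumulation",
    "fraction_reduced",
    "partition_sediment",
    "PartitionResult",
]

#: R^2 differences below this are treated as ties when ranking windows.
_R2_TIE_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class RateEstimate:
    """OLS slope of Fe(II) vs time over an exponential-phase window."""

    slope_mM_per_day: float
    intercept_mM: float
    window: tuple[float, float]
    n_points: int
    r_squared: float
    slope_stderr: float

    def __post_init__(self) -> None:
        if not self.window[0] < self.window[1]:
            raise ValueError("window start must precede window end")
        if self.n_points < 3:
            raise ValueError("a rate estimate needs at least 3 points")


def _window_r2(t: np.ndarray, log_density: np.ndarray) -> float:
    """R^2 of the OLS line log10(N) ~ t; -inf for zero-variance windows."""
    ss_tot = float(np.sum((log_density - log_density.mean()) ** 2))
    if ss_tot == 0.0:
        return -np.inf
    slope, intercept = np.polyfit(t, log_density, 1)
    resid = log_density - (slope * t + intercept)
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def select_exponential_window(
    series: CultureSeries, min_points: int = 3
) -> tuple[float, float]:
    """Best log-linear contiguous window of the growth curve.

    Enumerates every contiguous window of at least ``min_points`` observed
    timepoints with recorded cell density, fits log10(density) vs time, and
    returns the window with the highest R^2.  Ties (within 1e-9) are broken
    toward the longer window, then the earlier start.
    """
    if series.cell_density is None:
        raise ValueError("series has no cell density measurements")
    mask = ~np.isnan(series.cell_density)
    t = series.time_days[mask]
    dens = series.cell_density[mask]
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} timepoints with cell density")
    if np.any(dens <= 0):
        raise ValueError("cell densities must be positive for log-linear fitting")
    if np.all(dens == dens[0]):
        raise ValueError("cell density is constant; no exponential phase")
    logd = np.log10(dens)

    best: tuple[float, int, float] | None = None  # (r2, length, -start_time)
    best_window: tuple[float, float] | None = None
    n = t.size
    for i in range(n):
        for j in range(i + min_points - 1, n):
            r2 = _window_r2(t[i : j + 1], logd[i : j + 1])
            if r2 == -np.inf:
                continue
            key = (r2, j - i + 1, -t[i])
            if best is None or _better(key, best):
                best = key
                best_window = (float(t[i]), float(t[j]))
    if best_window is None:
        raise ValueError("no window with density variation found")
    return best_window


def _better(candidate: tuple[float, int, float], incumbent: tuple[float, int, float]) -> bool:
    if candidate[0] > incumbent[0] + _R2_TIE_TOL:
        return True
    if candidate[0] < incumbent[0] - _R2_TIE_TOL:
        return False
    return candidate[1:] > incumbent[1:]


def fe2_production_rate(
    series: CultureSeries, window: tuple[float, float] | None = None
) -> RateEstimate:
    """OLS slope of total Fe(II) (mM) vs time (days) in a window.

    ``window`` defaults to the auto-selected exponential-phase window of the
    growth curve; endpoints are inclusive.
    """
    if window is None:
        window = select_exponential_window(series)
    t0, t1 = window
    mask = (series.time_days >= t0) & (series.time_days <= t1) & ~np.isnan(series.fe2_total_mM)
    t = series.time_days[mask]
    fe2 = series.fe2_total_mM[mask]
    if t.size < 3:
        raise ValueError("window contains fewer than 3 Fe(II) observations")
    res = stats.linregress(t, fe2)
    r2 = float(res.rvalue**2) if not np.isnan(res.rvalue) else 0.0
    return RateEstimate(
        slope_mM_per_day=float(res.slope),
        intercept_mM=float(res.intercept),
        window=(float(t[0]), float(t[-1])),
        n_points=int(t.size),
        r_squared=r2,
        slope_stderr=float(res.stderr),
    )


def final_accumulation(series: CultureSeries, k_last: int = 2) -> float:
    """Stationary-phase Fe(II): mean of the last ``k_last`` total-Fe(II) values."""
    if k_last < 1:
        raise ValueError("k_last must be >= 1")
    fe2 = series.fe2_total_mM[~np.isnan(series.fe2_total_mM)]
    if fe2.size < k_last:
        raise ValueError(f"series has fewer than {k_last} Fe(II) observations")
    return float(np.mean(fe2[-k_last:]))


def fraction_reduced(fe2_final_mM: float, fe3_initial_mM: float) -> float:
    """Percent of the initial Fe(III) loading recovered as Fe(II)."""
    if fe3_initial_mM <= 0:
        raise ZeroDivisionError("fraction reduced undefined for zero Fe(III) input")
    if fe2_final_mM < 0:
        raise ValueError("fe2_final_mM must be >= 0")
    return 100.0 * fe2_final_mM / fe3_initial_mM


class PartitionResult(NamedTuple):
    sediment_mM: float
    over_subtraction: bool


def partition_sediment(total_mM: float, supernatant_mM: float) -> PartitionResult:
    """Sediment-associated fraction: total minus soluble, clamped at zero.

    Supernatant exceeding total by more than the assay tolerance is flagged
    (not fatal): small over-subtractions are expected from replicate noise.
    """
    if total_mM < 0 or supernatant_mM < 0:
        raise ValueError("concentrations must be >= 0")
    sediment = total_mM - supernatant_mM
    if sediment < 0:
        return PartitionResult(0.0, supernatant_mM - total_mM > TOLERANCE_MM)
    return PartitionResult(sediment, False)


def series_report(series_list: Sequence[CultureSeries], k_last: int = 2):
    """Per-series kinetics summary table (one row per replicate).

    Columns: identity, fitted rate with stderr/R^2/window, stationary
    accumulation, percent of Fe(III) reduced, and the soluble/sediment split
    of the final timepoint where soluble Fe(II) was measured.
    """
    import pandas as pd

    rows = []
    for s in series_list:
        row: dict = {
            "species": s.species,
            "condition": s.condition,
            "mineral": s.mineral,
            "replicate": s.replicate_id,
        }
        try:
            est = fe2_production_rate(s)
            row.update(
                rate_mM_per_day=est.slope_mM_per_day,
                rate_stderr=est.slope_stderr,
                r_squared=est.r_squared,
                window_start=est.window[0],
                window_end=est.window[1],
            )
        except ValueError:
            row.update(
                rate_mM_per_day=np.nan,
                rate_stderr=np.nan,
                r_squared=np.nan,
                window_start=np.nan,
                window_end=np.nan,
            )
        final = final_accumulation(s, k_last=k_last)
        row["final_fe2_mM"] = final
        row["pct_fe_reduced"] = (
            fraction_reduced(final, s.fe3_initial_mM) if s.fe3_initial_mM > 0 else np.nan
        )
        if s.fe2_soluble_mM is not None and not np.isnan(s.fe2_soluble_mM[-1]):
            soluble = float(s.fe2_soluble_mM[-1])
            row["final_soluble_mM"] = soluble
            row["final_sediment_mM"] = partition_sediment(
                float(s.fe2_total_mM[-1]), soluble
            ).sediment_mM
        else:
            row["final_soluble_mM"] = np.nan
            row["final_sediment_mM"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
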