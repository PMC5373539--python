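"""Gompertz growth-curve fitting and substrate-use calls for EcoPlate data.

The model is the modified Gompertz sigmoid in the Zwietering parameterization,

    y(t) = A * exp(-exp(mu_max * e / A * (lam - t) + 1)) + y0

with A the asymptotic rise above the initial density (carrying capacity, OD
units), mu_max the maximum slope (OD/day), lam the lag time (days) and y0 the
initial density.  By construction the maximum derivative of the fitted curve
equals mu_max and the tangent at the inflection point crosses y = y0 at
t = lam.

A substrate counts as utilized when the replicate-mean OD590 at the final
sampling day (day 10) is at or above a fixed threshold (default 0.30 OD,
chosen to exceed the carbon-free control wells).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GrowthCurve",
    "GompertzFit",
    "UseCall",
    "InsufficientDataError",
    "DEFAULT_USE_THRESHOLD",
    "DEFAULT_EXCLUDED_ISOLATES",
    "CONTROL_SUBSTRATE",
    "gompertz",
    "average_replicates",
    "fit_gompertz",
    "call_substrate_use",
    "substrate_richness",
    "mean_trait_across_temperatures",
]

DEFAULT_USE_THRESHOLD = 0.30
#: Isolate removed from all plate analyses because its carbon-free control
#: wells developed pigment, invalidating the OD590 threshold for it.
DEFAULT_EXCLUDED_ISOLATES = ("Sanguibacter sp.",)
#: Substrate name reserved for the carbon-free control wells.
CONTROL_SUBSTRATE = "control"


class InsufficientDataError(ValueError):
    """Raised when a curve has too few time points to fit."""


@dataclass(frozen=True)
class GrowthCurve:
    """Replicate-averaged OD590 trajectory for one isolate x substrate x temperature."""

    isolate: str
    substrate: str
    temperature_c: float
    days: tuple[float, ...]
    od590_mean: tuple[float, ...]
    n_replicates: int

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        if len(days) != len(self.od590_mean):
            raise ValueError("days and od590_mean length mismatch")
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(np.asarray(self.od590_mean) < 0):
            raise ValueError("OD590 values must be nonnegative")


@dataclass(frozen=True)
class GompertzFit:
    A: float
    mu_max: float
    lam: float
    y0: float
    rss: float
    converged: bool
    degenerate: bool = False

    def predict(self, t: np.ndarray) -> np.ndarray:
        return gompertz(np.asarray(t, dtype=float), self.A, self.mu_max, self.lam, self.y0)


@dataclass(frozen=True)
class UseCall:
    isolate: str
    substrate: str
    temperature_c: float
    final_od590_mean: float
    used: bool
    threshold: float
    endpoint_day: float
    endpoint_is_fallback: bool = False


def gompertz(t: np.ndarray, A: float, mu_max: float, lam: float, y0: float) -> np.ndarray:
    """Modified Gompertz curve; A must be positive.

    The inner exponent is clipped at 700 so extreme optimizer trial points
    underflow to y0 instead of overflowing (exp(-inf) -> 0 either way).
    """
    inner = np.clip(mu_max * math.e / A * (lam - t) + 1.0, None, 700.0)
    return A * np.exp(-np.exp(inner)) + y0


def average_replicates(plate_records: pd.DataFrame) -> list[GrowthCurve]:
    """Collapse replicate wells to one mean OD590 trajectory per curve.

    Expects long-format records with columns (isolate, substrate,
    temperature_c, replicate, day, od590).  A time point missing from every
    replicate is reported as a gap warning; the curve is still produced from
    the days that are present.
    """
    required = {"isolate", "substrate", "temperature_c", "replicate", "day", "od590"}
    missing = required - set(plate_records.columns)
    if missing:
        raise ValueError(f"plate records missing columns: {sorted(missing)}")

    all_days = np.sort(plate_records["day"].unique())
    curves: list[GrowthCurve] = []
    for (isolate, substrate, temp), grp in plate_records.groupby(
            ["isolate", "substrate", "temperature_c"], sort=True):
        means = grp.groupby("day")["od590"].mean().sort_index()
        gaps = set(all_days) - set(means.index)
        if gaps:
            warnings.warn(
                f"{isolate}/{substrate}@{temp}C: no replicate observed on days {sorted(gaps)}")
        curves.append(GrowthCurve(
            isolate=str(isolate), substrate=str(substrate), temperature_c=float(temp),
            days=tuple(float(d) for d in means.index),
            od590_mean=tuple(float(v) for v in means.to_numpy()),
            n_replicates=int(grp["replicate"].nunique()),
        ))
    return curves


def _heuristic_p0(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    y0 = float(y[0])
    A = max(float(y.max() - y[0]), 1e-6)
    slopes = np.diff(y) / np.diff(t)
    mu = max(float(slopes.max()), 1e-6)
    above = np.nonzero(y > y0 + 0.05 * A)[0]
    lam = float(t[above[0]]) if len(above) else 0.0
    return A, mu, lam, y0


def fit_gompertz(curve: GrowthCurve,
                 init_strategy: str | Sequence[float] = "heuristic") -> GompertzFit:
    """Nonlinear least-squares fit of the modified Gompertz model.

    ``init_strategy`` is either "heuristic" (y0 = first OD, A = rise above it,
    mu_max = steepest two-point slope, lam = first time OD exceeds
    y0 + 0.05 A) or an explicit (A, mu_max, lam, y0) starting point.
    All parameters are bounded below by 0; A is capped at twice the maximum
    observed OD to keep flat curves from running away.  Non-convergence is
    reported through the flag, not an exception; an exactly constant curve is
    returned as a degenerate zero-rate fit.
    """
    t = np.asarray(curve.days, dtype=float)
    y = np.asarray(curve.od590_mean, dtype=float)
    if len(t) < 5:
        raise InsufficientDataError(f"need >= 5 time points, have {len(t)}")

    if np.ptp(y) == 0.0:
        return GompertzFit(A=0.0, mu_max=0.0, lam=0.0, y0=float(y[0]),
                           rss=0.0, converged=False, degenerate=True)

    if isinstance(init_strategy, str):
        if init_strategy != "heuristic":
            raise ValueError(f"unknown init strategy: {init_strategy!r}")
        p0 = _heuristic_p0(t, y)
    else:
        p0 = tuple(float(v) for v in init_strategy)
        if len(p0) != 4:
            raise ValueError("explicit init must be (A, mu_max, lam, y0)")

    ymax = float(y.max())
    lower = (1e-9, 0.0, 0.0, 0.0)
    upper = (2.0 * ymax, np.inf, np.inf, max(ymax, 1e-9))
    p0 = tuple(np.clip(p0, lower, [2.0 * ymax, 1e9, 1e9, max(ymax, 1e-9)]))
    try:
        popt, _ = curve_fit(gompertz, t, y, p0=p0, bounds=(lower, upper),
                            maxfev=20000)
        converged = True
    except RuntimeError:
        popt = np.asarray(p0)
        converged = False
    rss = float(np.sum((gompertz(t, *popt) - y) ** 2))
    return GompertzFit(A=float(popt[0]), mu_max=float(popt[1]), lam=float(popt[2]),
                       y0=float(popt[3]), rss=rss, converged=converged)


def call_substrate_use(curve: GrowthCurve, threshold: float = DEFAULT_USE_THRESHOLD,
                       final_day: float = 10.0) -> UseCall:
    """Apply the final-day OD590 threshold rule (inclusive: mean >= threshold).

    If the nominal final day was never observed the last available day is used
    and the call is flagged as a fallback.
    """
    if len(curve.days) == 0:
        raise ValueError("curve has no observations")
    days = np.asarray(curve.days)
    hit = np.nonzero(days == final_day)[0]
    if len(hit):
        idx, fallback = int(hit[0]), False
    else:
        idx, fallback = len(days) - 1, True
    final = float(curve.od590_mean[idx])
    return UseCall(isolate=curve.isolate, substrate=curve.substrate,
                   temperature_c=curve.temperature_c, final_od590_mean=final,
                   used=final >= threshold, threshold=threshold,
                   endpoint_day=float(days[idx]), endpoint_is_fallback=fallback)


def substrate_richness(use_calls: Iterable[UseCall], isolate: str, temperature_c: float,
                       excluded_isolates: Sequence[str] = ()) -> int:
    """Number of substrates called used for one isolate at one temperature."""
    if isolate in excluded_isolates:
        raise KeyError(f"isolate {isolate!r} is excluded from plate analyses")
    calls = [c for c in use_calls
             if c.isolate == isolate and c.temperature_c == temperature_c
             and c.substrate != CONTROL_SUBSTRATE]
    if not calls:
        raise KeyError(f"no use calls for isolate {isolate!r} at {temperature_c} C")
    return sum(c.used for c in calls)


def mean_trait_across_temperatures(values: Sequence[float]) -> float:
    """Arithmetic mean over the non-missing per-temperature values.

    Returns NaN (a missing result, not an error) when every value is missing.
    """
    arr = np.asarray(list(values), dtype=float)
    if len(arr) == 0 or np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))
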