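"""Q10 temperature-sensitivity statistics and CO2 microcosm bookkeeping.

Q10 is the factor by which a biological rate changes per 10 degC warming.
From rates measured at two temperatures,

    Q10 = (rate_warm / rate_cold) ** (10 / (t_warm - t_cold))

and, for litter decomposition measured as the time to respire a fixed amount
of CO2, equivalently

    Q10 = (time_cold / time_warm) ** (10 / (t_warm - t_cold))

since the effective rate is inversely proportional to the time to threshold.
All Q10s here use the warm-over-cold rate orientation, so faster-when-warmer
gives Q10 > 1.  Only the extreme temperatures (defaults 18 and 26 degC) enter
a Q10; intermediate treatments are summarized elsewhere.

Zero rates need care: activity at the warm temperature only makes the ratio
infinite (flagged invalid, "undefined-at-cold" -- such values are not
comparable to ordinary Q10s); activity at the cold temperature only gives a
valid Q10 of 0, flagged "warm-inactive" for review; no activity at either
temperature is invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Q10Result",
    "Co2Series",
    "ThresholdCrossing",
    "DEFAULT_CO2_THRESHOLD_PPM",
    "DEFAULT_AMBIENT_BASELINE_PPM",
    "q10_rate",
    "q10_yield",
    "cumulate_co2",
    "time_to_threshold",
    "q10_decomposition",
    "ppm_to_percent_litter_c",
]

DEFAULT_CO2_THRESHOLD_PPM = 5000.0
DEFAULT_AMBIENT_BASELINE_PPM = 400.0

_R_L_ATM = 0.0820574  # gas constant, L*atm/(mol*K)
_MOLAR_MASS_C = 12.011  # g/mol


@dataclass(frozen=True)
class Q10Result:
    value: float
    kind: str  # one of {"mu_max", "od590", "decomposition"}
    t_cold: float
    t_warm: float
    valid: bool
    reason: str = ""


@dataclass(frozen=True)
class Co2Series:
    """Cumulative headspace CO2 for one microcosm (or replicate mean)."""

    isolate: str
    temperature_c: float
    replicate: int | None
    days: tuple[float, ...]
    cumulative_ppm: tuple[float, ...]

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        cum = np.asarray(self.cumulative_ppm, dtype=float)
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(np.diff(cum) < 0):
            raise ValueError("cumulative_ppm must be nondecreasing")


@dataclass(frozen=True)
class ThresholdCrossing:
    """Time (days) at which a cumulative CO2 series first crosses a threshold."""

    days: float | None
    reached: bool
    reason: str = ""


def _q10(ratio_warm_over_cold: float, t_cold: float, t_warm: float) -> float:
    return float(ratio_warm_over_cold ** (10.0 / (t_warm - t_cold)))


def _q10_from_rates(rate_cold: float, rate_warm: float, t_cold: float, t_warm: float,
                    kind: str) -> Q10Result:
    if t_warm <= t_cold:
        raise ValueError("t_warm must exceed t_cold")
    if rate_cold < 0 or rate_warm < 0:
        raise ValueError("rates must be nonnegative")
    if rate_cold == 0.0 and rate_warm == 0.0:
        return Q10Result(float("nan"), kind, t_cold, t_warm, False, "no-activity")
    if rate_cold == 0.0:
        return Q10Result(float("inf"), kind, t_cold, t_warm, False, "undefined-at-cold")
    reason = "warm-inactive" if rate_warm == 0.0 else ""
    return Q10Result(_q10(rate_warm / rate_cold, t_cold, t_warm), kind,
                     t_cold, t_warm, True, reason)


def q10_rate(rate_cold: float, rate_warm: float, t_cold: float = 18.0,
             t_warm: float = 26.0) -> Q10Result:
    """Growth-rate Q10 from mu_max estimates at the cold and warm extremes."""
    return _q10_from_rates(rate_cold, rate_warm, t_cold, t_warm, "mu_max")


def q10_yield(od_cold: float, od_warm: float, t_cold: float = 18.0,
              t_warm: float = 26.0) -> Q10Result:
    """Substrate-yield Q10 from mean final-day OD590 at the two extremes."""
    return _q10_from_rates(od_cold, od_warm, t_cold, t_warm, "od590")


def cumulate_co2(days, ppm_measured, ambient_baseline_ppm: float = DEFAULT_AMBIENT_BASELINE_PPM
                 ) -> np.ndarray:
    """Running sum of above-ambient headspace CO2 across sampling events.

    Microcosms are vented to ambient between samplings, so each measurement is
    one accumulation interval; increments are clamped at zero (a reading at or
    below ambient contributes nothing).
    """
    days = np.asarray(days, dtype=float)
    ppm = np.asarray(ppm_measured, dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("measurements must be ordered by strictly increasing day")
    if np.any(ppm < 0):
        raise ValueError("negative raw CO2 concentration")
    return np.cumsum(np.maximum(ppm - ambient_baseline_ppm, 0.0))


def time_to_threshold(days, cumulative_ppm,
                      threshold_ppm: float = DEFAULT_CO2_THRESHOLD_PPM) -> ThresholdCrossing:
    """First crossing time of a cumulative series, by linear interpolation.

    The series is anchored at (day 0, 0 ppm); an exact hit returns that
    sampling day; a series that never reaches the threshold is flagged
    "not-reached" -- no extrapolation beyond the observed window.
    """
    days = np.concatenate([[0.0], np.asarray(days, dtype=float)])
    cum = np.concatenate([[0.0], np.asarray(cumulative_ppm, dtype=float)])
    if np.any(np.diff(cum) < 0):
        raise ValueError("cumulative series must be nondecreasing")
    at_or_above = np.nonzero(cum >= threshold_ppm)[0]
    if len(at_or_above) == 0:
        return ThresholdCrossing(None, False, "not-reached")
    i = int(at_or_above[0])
    if cum[i] == threshold_ppm or i == 0:
        return ThresholdCrossing(float(days[i]), True)
    frac = (threshold_ppm - cum[i - 1]) / (cum[i] - cum[i - 1])
    return ThresholdCrossing(float(days[i - 1] + frac * (days[i] - days[i - 1])), True)


def q10_decomposition(time_cold: float | ThresholdCrossing,
                      time_warm: float | ThresholdCrossing,
                      t_cold: float = 18.0, t_warm: float = 26.0) -> Q10Result:
    """Decomposition Q10 from times to a fixed cumulative-CO2 threshold.

    Dividing the cold time by the warm time and raising to 10/(t_warm-t_cold)
    corrects for the actual incubation differential.  A "not-reached" crossing
    at either temperature propagates as an invalid result.
    """
    times = []
    for t in (time_cold, time_warm):
        if isinstance(t, ThresholdCrossing):
            if not t.reached:
                return Q10Result(float("nan"), "decomposition", t_cold, t_warm,
                                 False, t.reason or "not-reached")
            times.append(t.days)
        else:
            times.append(float(t))
    if times[0] <= 0 or times[1] <= 0:
        raise ValueError("times to threshold must be positive")
    if t_warm <= t_cold:
        raise ValueError("t_warm must exceed t_cold")
    return Q10Result(_q10(times[0] / times[1], t_cold, t_warm), "decomposition",
                     t_cold, t_warm, True)


def ppm_to_percent_litter_c(ppm: float, headspace_ml: float, litter_mg: float,
                            carbon_fraction: float, temp_c: float) -> float:
    """Percent of litter carbon respired, from a cumulative CO2 mixing ratio.

    Ideal-gas conversion at 1 atm: a mixing ratio of ``ppm`` in a headspace of
    ``headspace_ml`` corresponds to ppm*1e-6*V of CO2 by volume, hence
    PV/(RT) moles, each carrying one carbon atom.
    """
    if headspace_ml <= 0 or litter_mg <= 0:
        raise ValueError("headspace volume and litter mass must be positive")
    if not (0.0 < carbon_fraction <= 1.0):
        raise ValueError("carbon_fraction must be in (0, 1]")
    if ppm < 0:
        raise ValueError("ppm must be nonnegative")
    moles = (ppm * 1e-6) * (headspace_ml / 1000.0) / (_R_L_ATM * (temp_c + 273.15))
    grams_c = moles * _MOLAR_MASS_C
    litter_c_g = litter_mg * 1e-3 * carbon_fraction
    return float(100.0 * grams_c / litter_c_g)
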