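"""Cross-trait summaries: OLS correlations, z-score normalization, PCA,
and assembly of the per-isolate functional/response trait matrix.

The trait matrix has one row per (non-excluded) isolate and seven columns:
three functional traits (mean mu_max, mean final OD590, substrate richness,
plus cumulative CO2 as the litter-decomposition trait) and three temperature
response traits (Q10 of mu_max, of final OD590, and of decomposition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .plate_growth import mean_trait_across_temperatures

__all__ = [
    "TRAIT_COLUMNS",
    "CorrelationResult",
    "PcaResult",
    "correlate_traits",
    "normalize_traits",
    "pca",
    "build_trait_table",
]

TRAIT_COLUMNS = (
    "mean_mu_max", "mean_od590", "richness", "cumulative_co2",
    "q10_mu_max", "q10_od590", "q10_decomposition",
)


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    p: float
    slope: float
    intercept: float
    n: int


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # rows = observations, columns PC1..PCk
    loadings: pd.DataFrame  # rows = traits, columns PC1..PCk
    percent_variance: np.ndarray  # sums to 100


def correlate_traits(x, y) -> CorrelationResult:
    """Ordinary least squares of y on x over paired non-missing values.

    The slope p-value is the classical two-sided t test with n-2 degrees of
    freedom.  R-squared and p are symmetric in x and y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 paired values, have {len(x)}")
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return CorrelationResult(r_squared=float(res.rvalue ** 2), p=float(res.pvalue),
                             slope=float(res.slope), intercept=float(res.intercept),
                             n=len(x))


def normalize_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column z-scores over non-missing entries (mean 0, sample SD 1).

    Missing entries stay missing; constant columns are dropped with a warning.
    """
    out = {}
    for col in table.columns:
        vals = table[col].astype(float)
        sd = vals.std(ddof=1, skipna=True)
        if not np.isfinite(sd) or sd == 0.0:
            warnings.warn(f"dropping constant trait column {col!r}")
            continue
        out[col] = (vals - vals.mean(skipna=True)) / sd
    return pd.DataFrame(out, index=table.index)


def pca(normalized_table: pd.DataFrame) -> PcaResult:
    """PCA of the complete-case submatrix via SVD of the centered data.

    Components are ordered by decreasing explained variance;
    ``percent_variance`` sums to 100.  Rows with any missing trait are
    dropped (complete-case deletion).
    """
    complete = normalized_table.dropna(axis=0, how="any")
    if complete.shape[0] < 3 or complete.shape[1] < 2:
        raise ValueError("need >= 3 complete rows and >= 2 columns for PCA")
    X = complete.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(X.shape[0] - 1, X.shape[1])
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    var = S ** 2
    pcs = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(U * S, index=complete.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=complete.columns, columns=pcs),
        percent_variance=100.0 * var / var.sum(),
    )


def build_trait_table(fits: pd.DataFrame, use_calls: pd.DataFrame,
                      q10s: pd.DataFrame, co2_summaries: pd.DataFrame,
                      exclusions: tuple[str, ...] = (),
                      richness_aggregation: str = "any") -> pd.DataFrame:
    """Assemble the per-isolate functional/response trait matrix.

    Inputs are the tidy stage outputs:
      fits          -- (isolate, substrate, temperature_c, mu_max, ...) for
                       utilized combinations only;
      use_calls     -- (isolate, substrate, temperature_c, final_od590_mean, used);
      q10s          -- (isolate, kind, value, valid), kinds mu_max/od590/decomposition;
      co2_summaries -- (isolate, temperature_c, cumulative_ppm) final cumulative CO2.

    Functional plate traits average first across utilized substrates within a
    temperature, then across temperatures.  Richness counts substrates used
    at any temperature ("any") or used on average across temperatures
    ("mean_od"); per-substrate Q10s are averaged over valid values.
    Missing values propagate as NaN, never as zero.
    """
    isolates = sorted(set(use_calls["isolate"]) | set(co2_summaries["isolate"]))
    isolates = [i for i in isolates if i not in exclusions]
    if len(isolates) != len(set(isolates)):
        raise ValueError("isolate id collision")

    rows = []
    for iso in isolates:
        f = fits[fits["isolate"] == iso]
        u = use_calls[(use_calls["isolate"] == iso)]
        u = u[u["substrate"] != "control"]
        q = q10s[(q10s["isolate"] == iso) & q10s["valid"]]
        c = co2_summaries[co2_summaries["isolate"] == iso]

        per_temp_mu = f.groupby("temperature_c")["mu_max"].mean() if len(f) else pd.Series(dtype=float)
        used_od = u[u["used"]]
        per_temp_od = (used_od.groupby("temperature_c")["final_od590_mean"].mean()
                       if len(used_od) else pd.Series(dtype=float))

        if richness_aggregation == "any":
            richness = int(u.groupby("substrate")["used"].any().sum()) if len(u) else np.nan
        elif richness_aggregation == "mean_od":
            thresh = float(u["threshold"].iloc[0]) if "threshold" in u and len(u) else 0.30
            richness = (int((u.groupby("substrate")["final_od590_mean"].mean()
                             >= thresh).sum()) if len(u) else np.nan)
        else:
            raise ValueError(f"unknown richness_aggregation: {richness_aggregation!r}")

        rows.append({
            "isolate": iso,
            "mean_mu_max": mean_trait_across_temperatures(per_temp_mu.to_numpy()),
            "mean_od590": mean_trait_across_temperatures(per_temp_od.to_numpy()),
            "richness": richness,
            "cumulative_co2": mean_trait_across_temperatures(
                c["cumulative_ppm"].to_numpy()) if len(c) else np.nan,
            "q10_mu_max": _mean_or_nan(q[q["kind"] == "mu_max"]["value"]),
            "q10_od590": _mean_or_nan(q[q["kind"] == "od590"]["value"]),
            "q10_decomposition": _mean_or_nan(q[q["kind"] == "decomposition"]["value"]),
        })
    return pd.DataFrame(rows).set_index("isolate")[list(TRAIT_COLUMNS)]


def _mean_or_nan(values: pd.Series) -> float:
    vals = values.to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if len(vals) else float("nan")
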