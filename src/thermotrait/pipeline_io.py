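"""File formats, run configuration and end-to-end orchestration.

The pipeline runs the whole analysis in one deterministic pass:

    plate/CO2 tables (read or simulated)
      -> replicate-averaged growth curves -> use calls -> Gompertz fits
      -> Q10 response traits (growth rate, yield, decomposition)
      -> per-isolate trait matrix
      -> Blomberg's K permutation tests, Mantel tests on distance matrices
      -> trait correlations and PCA

Every output table can be written as TSV next to a JSON manifest recording
the configuration, seed, per-stage record counts, warnings and content
hashes, so two runs with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import plate_growth, temperature_response, phylo_signal, trait_analysis
from .phylo_signal import PhyloTree
from .plate_growth import CONTROL_SUBSTRATE, DEFAULT_EXCLUDED_ISOLATES
from .synthetic_data import SimulationConfig, simulate_study

__all__ = [
    "RunConfig",
    "PipelineResult",
    "read_newick",
    "read_plate_csv",
    "read_co2_csv",
    "run_pipeline",
]

PLATE_COLUMNS = ("isolate", "substrate", "temperature_c", "replicate", "day",
                 "od590", "od750")
CO2_COLUMNS = ("isolate", "temperature_c", "replicate", "day", "co2_ppm")


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run."""

    tree_path: str | None = None
    plate_path: str | None = None
    co2_path: str | None = None
    simulation: SimulationConfig | None = None
    functional_mode: str = "bm"  # trait architecture when simulating
    q10_mode: str = "white"
    temperatures: tuple[float, ...] = (18.0, 22.0, 26.0)
    use_threshold: float = 0.30
    final_day: float = 10.0
    co2_threshold_ppm: float = 5000.0
    ambient_baseline_ppm: float = 400.0
    n_perm: int = 999
    seed: int = 0
    exclusions: tuple[str, ...] = DEFAULT_EXCLUDED_ISOLATES
    richness_aggregation: str = "any"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.use_threshold <= 0 or self.co2_threshold_ppm <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if len(self.temperatures) < 2 or np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing, with a "
                             "cold/warm pair for Q10")

    @property
    def t_cold(self) -> float:
        return float(min(self.temperatures))

    @property
    def t_warm(self) -> float:
        return float(max(self.temperatures))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sim is not None:
            cfg.simulation = SimulationConfig(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()})
        return cfg


@dataclass
class PipelineResult:
    tree: PhyloTree
    fits: pd.DataFrame
    use_calls: pd.DataFrame
    q10s: pd.DataFrame
    co2_summaries: pd.DataFrame
    trait_table: pd.DataFrame
    phylosignal: pd.DataFrame
    mantel: pd.DataFrame
    correlations: pd.DataFrame
    pca: trait_analysis.PcaResult | None
    manifest: dict
    ground_truth: dict | None = None


def read_newick(path: str | Path) -> PhyloTree:
    """Read one rooted Newick tree.

    An unrooted tree (basal polytomy without an explicit rooting statement)
    is midpoint-rooted with a warning.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    if not tree.is_rooted and len(tree.seed_node.child_nodes()) > 2:
        warnings.warn(f"{path}: tree appears unrooted; midpoint-rooting")
        tree.reroot_at_midpoint(update_bipartitions=False)
    tree.is_rooted = True
    return tree


def _read_table(path: str | Path, columns: tuple[str, ...],
                nonnegative: tuple[str, ...]) -> tuple[pd.DataFrame, dict]:
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(columns)
    missing = set(columns) - set(df.columns)
    errors = []
    if missing:
        errors.append(f"missing columns: {sorted(missing)}")
    if unknown:
        errors.append(f"unknown columns: {sorted(unknown)}")
    for col in nonnegative:
        if col in df.columns:
            bad = df.index[df[col] < 0].tolist()
            if bad:
                errors.append(f"negative {col} in rows {bad[:10]}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    report = {
        "n_records": int(len(df)),
        "n_missing_cells": int(df.isna().sum().sum()),
        "isolates": sorted(map(str, df["isolate"].unique())),
    }
    return df, report


def read_plate_csv(path: str | Path,
                   expected_days: tuple[float, ...] | None = None
                   ) -> tuple[pd.DataFrame, dict]:
    """Read and validate a long-format plate CSV."""
    df, report = _read_table(path, PLATE_COLUMNS, ("od590", "od750", "day"))
    if expected_days is not None:
        extra = sorted(set(df["day"]) - set(expected_days))
        if extra:
            warnings.warn(f"{path}: days outside the declared sampling set "
                          f"retained: {extra}")
            report["unexpected_days"] = extra
    return df, report


def read_co2_csv(path: str | Path,
                 expected_days: tuple[float, ...] | None = None
                 ) -> tuple[pd.DataFrame, dict]:
    """Read and validate a long-format microcosm CO2 CSV."""
    df, report = _read_table(path, CO2_COLUMNS, ("co2_ppm", "day"))
    if expected_days is not None:
        extra = sorted(set(df["day"]) - set(expected_days))
        if extra:
            warnings.warn(f"{path}: days outside the declared sampling set "
                          f"retained: {extra}")
            report["unexpected_days"] = extra
    return df, report


def _stage_seed(seed: int, label: str) -> int:
    """Deterministic per-stage sub-seed (single seeded stream, fanned out)."""
    key = zlib.crc32(label.encode("utf8")) % (2 ** 31)
    return int(np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(key,))).integers(2 ** 31))


def _fit_used_curves(curves, use_by_key, config) -> pd.DataFrame:
    rows = []
    for c in curves:
        key = (c.isolate, c.substrate, c.temperature_c)
        if not use_by_key.get(key, False):
            continue
        fit = plate_growth.fit_gompertz(c)
        rows.append({"isolate": c.isolate, "substrate": c.substrate,
                     "temperature_c": c.temperature_c, "A": fit.A,
                     "mu_max": fit.mu_max, "lam": fit.lam, "y0": fit.y0,
                     "rss": fit.rss, "converged": fit.converged,
                     "degenerate": fit.degenerate})
    return pd.DataFrame(rows, columns=["isolate", "substrate", "temperature_c",
                                       "A", "mu_max", "lam", "y0", "rss",
                                       "converged", "degenerate"])


def _q10_tables(fits, use_calls, co2, config) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-substrate growth/yield Q10s and per-isolate decomposition Q10s."""
    tc, tw = config.t_cold, config.t_warm
    rows = []

    used = use_calls[use_calls["substrate"] != CONTROL_SUBSTRATE]
    for (iso, sub), grp in used.groupby(["isolate", "substrate"]):
        at = {r["temperature_c"]: r for _, r in grp.iterrows()}
        cold, warm = at.get(tc), at.get(tw)
        if cold is None or warm is None:
            continue
        if not (cold["used"] or warm["used"]):
            continue  # substrate not utilized at either extreme: no Q10

        fit_at = {r["temperature_c"]: r for _, r in
                  fits[(fits["isolate"] == iso) & (fits["substrate"] == sub)].iterrows()}
        mu_cold = float(fit_at[tc]["mu_max"]) if cold["used"] and tc in fit_at else 0.0
        mu_warm = float(fit_at[tw]["mu_max"]) if warm["used"] and tw in fit_at else 0.0
        for kind, res in (
                ("mu_max", temperature_response.q10_rate(mu_cold, mu_warm, tc, tw)),
                ("od590", temperature_response.q10_yield(
                    float(cold["final_od590_mean"]) if cold["used"] else 0.0,
                    float(warm["final_od590_mean"]), tc, tw))):
            rows.append({"isolate": iso, "substrate": sub, "kind": kind,
                         "value": res.value, "valid": res.valid, "reason": res.reason})

    co2_rows = []
    for (iso, temp), grp in co2.groupby(["isolate", "temperature_c"]):
        mean_by_day = grp.groupby("day")["co2_ppm"].mean().sort_index()
        cum = temperature_response.cumulate_co2(
            mean_by_day.index.to_numpy(), mean_by_day.to_numpy(),
            config.ambient_baseline_ppm)
        crossing = temperature_response.time_to_threshold(
            mean_by_day.index.to_numpy(), cum, config.co2_threshold_ppm)
        co2_rows.append({"isolate": iso, "temperature_c": float(temp),
                         "cumulative_ppm": float(cum[-1]),
                         "time_to_threshold": crossing.days,
                         "reached": crossing.reached})
    co2_summaries = pd.DataFrame(co2_rows, columns=[
        "isolate", "temperature_c", "cumulative_ppm", "time_to_threshold", "reached"])

    for iso, grp in co2_summaries.groupby("isolate"):
        at = {r["temperature_c"]: r for _, r in grp.iterrows()}
        if tc not in at or tw not in at:
            continue
        def _crossing(row):
            return temperature_response.ThresholdCrossing(
                row["time_to_threshold"], bool(row["reached"]),
                "" if row["reached"] else "not-reached")
        res = temperature_response.q10_decomposition(
            _crossing(at[tc]), _crossing(at[tw]), tc, tw)
        rows.append({"isolate": iso, "substrate": "litter", "kind": "decomposition",
                     "value": res.value, "valid": res.valid, "reason": res.reason})

    q10s = pd.DataFrame(rows, columns=["isolate", "substrate", "kind",
                                       "value", "valid", "reason"])
    return q10s, co2_summaries


def _per_substrate_profiles(fits, use_calls, q10s) -> dict[str, pd.DataFrame]:
    """Isolate x substrate profile matrices for the Mantel comparisons.

    Activity profiles (use flags, final OD590, mu_max) fill unused
    combinations with zero -- no use means zero measurable activity, so the
    profiles are complete and isolates with disjoint substrate sets remain
    comparable.  Q10 profiles keep unused/invalid entries missing (a Q10 of
    an unused substrate is undefined, not zero) and rely on pairwise
    deletion downstream.
    """
    used = use_calls[use_calls["substrate"] != CONTROL_SUBSTRATE]
    any_use = used.groupby(["isolate", "substrate"])["used"].any().unstack()

    profiles: dict[str, pd.DataFrame] = {"substrate_use": any_use.astype(float)}

    od = used[used["used"]].groupby(["isolate", "substrate"])["final_od590_mean"] \
        .mean().unstack()
    profiles["mean_od590"] = od.reindex(index=any_use.index,
                                        columns=any_use.columns).fillna(0.0)

    mu = fits.groupby(["isolate", "substrate"])["mu_max"].mean().unstack() \
        if len(fits) else pd.DataFrame(index=any_use.index)
    profiles["mean_mu_max"] = mu.reindex(index=any_use.index,
                                         columns=any_use.columns).fillna(0.0)

    for kind, name in (("mu_max", "q10_mu_max"), ("od590", "q10_od590")):
        sub = q10s[(q10s["kind"] == kind) & q10s["valid"]]
        prof = (sub.groupby(["isolate", "substrate"])["value"].mean().unstack()
                if len(sub) else pd.DataFrame(index=any_use.index))
        profiles[name] = prof.reindex(any_use.index)
    return profiles


def _phylo_tests(tree, trait_table, profiles, config) -> tuple[pd.DataFrame, pd.DataFrame]:
    k_rows = []
    for trait in trait_table.columns:
        series = trait_table[trait]
        seed = _stage_seed(config.seed, f"k:{trait}")
        try:
            res = phylo_signal.k_permutation_test(
                tree, series, n_perm=config.n_perm, seed=seed)
            k_rows.append({"trait": trait, "statistic": res.k, "p": res.p,
                           "n_perm": res.n_perm, "seed": seed,
                           "n_used": res.n_tips_used, "note": ""})
        except ValueError as exc:
            k_rows.append({"trait": trait, "statistic": np.nan, "p": np.nan,
                           "n_perm": config.n_perm, "seed": seed, "n_used": 0,
                           "note": str(exc)})

    pat = phylo_signal.patristic_distances(tree)
    m_rows = []
    for name, prof in profiles.items():
        seed = _stage_seed(config.seed, f"mantel:{name}")
        labels = [lab for lab in pat.index if lab in prof.index]
        try:
            tdist = phylo_signal.trait_distance_matrix(prof.loc[labels])
            res = phylo_signal.mantel(pat.loc[tdist.index, tdist.index], tdist,
                                      n_perm=config.n_perm, seed=seed)
            m_rows.append({"trait": name, "statistic": res.r, "p": res.p,
                           "n_perm": res.n_perm, "seed": seed,
                           "n_used": res.n_labels, "note": ""})
        except ValueError as exc:
            m_rows.append({"trait": name, "statistic": np.nan, "p": np.nan,
                           "n_perm": config.n_perm, "seed": seed, "n_used": 0,
                           "note": str(exc)})
    cols = ["trait", "statistic", "p", "n_perm", "seed", "n_used", "note"]
    return pd.DataFrame(k_rows, columns=cols), pd.DataFrame(m_rows, columns=cols)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; deterministic given (inputs, seed)."""
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        result = _run_pipeline_inner(config)
    caught.extend(str(w.message) for w in wlist)
    result.manifest["warnings"] = caught
    if config.out_dir is not None:
        _write_outputs(result, config)
    return result


def _run_pipeline_inner(config: RunConfig) -> PipelineResult:
    ground_truth = None
    if config.simulation is not None:
        study = simulate_study(config.simulation, config.functional_mode,
                               config.q10_mode)
        tree, plate, co2 = study["tree"], study["plate"], study["co2"]
        ground_truth = {"plate": study["plate_truth"], "co2": study["co2_truth"]}
        reports = {"plate": {"n_records": len(plate)}, "co2": {"n_records": len(co2)}}
    else:
        if not (config.tree_path and config.plate_path and config.co2_path):
            raise ValueError("provide either simulation settings or paths to "
                             "tree, plate and CO2 inputs")
        tree = read_newick(config.tree_path)
        plate, plate_report = read_plate_csv(config.plate_path)
        co2, co2_report = read_co2_csv(config.co2_path)
        reports = {"plate": plate_report, "co2": co2_report}

    # isolate exclusion applies to all plate analyses at load time
    plate = plate[~plate["isolate"].isin(config.exclusions)]

    curves = plate_growth.average_replicates(plate)
    calls = [plate_growth.call_substrate_use(c, config.use_threshold, config.final_day)
             for c in curves if c.substrate != CONTROL_SUBSTRATE]
    use_calls = pd.DataFrame([{
        "isolate": c.isolate, "substrate": c.substrate,
        "temperature_c": c.temperature_c, "final_od590_mean": c.final_od590_mean,
        "used": c.used, "threshold": c.threshold, "endpoint_day": c.endpoint_day,
        "endpoint_is_fallback": c.endpoint_is_fallback} for c in calls])

    use_by_key = {(c.isolate, c.substrate, c.temperature_c): c.used for c in calls}
    fits = _fit_used_curves(curves, use_by_key, config)
    q10s, co2_summaries = _q10_tables(fits, use_calls, co2, config)

    trait_table = trait_analysis.build_trait_table(
        fits, use_calls, q10s,
        co2_summaries[["isolate", "temperature_c", "cumulative_ppm"]],
        exclusions=config.exclusions,
        richness_aggregation=config.richness_aggregation)

    profiles = _per_substrate_profiles(fits, use_calls, q10s)
    phylosig, mantel_table = _phylo_tests(tree, trait_table, profiles, config)

    corr_rows = []
    for xname, yname in (("mean_mu_max", "q10_mu_max"),
                         ("cumulative_co2", "q10_decomposition")):
        try:
            cr = trait_analysis.correlate_traits(trait_table[xname], trait_table[yname])
            corr_rows.append({"x": xname, "y": yname, "r_squared": cr.r_squared,
                              "p": cr.p, "slope": cr.slope,
                              "intercept": cr.intercept, "n": cr.n})
        except ValueError as exc:
            corr_rows.append({"x": xname, "y": yname, "r_squared": np.nan,
                              "p": np.nan, "slope": np.nan, "intercept": np.nan,
                              "n": 0, "note": str(exc)})
    correlations = pd.DataFrame(corr_rows)

    try:
        pca_result = trait_analysis.pca(trait_analysis.normalize_traits(trait_table))
    except ValueError as exc:
        warnings.warn(f"PCA skipped: {exc}")
        pca_result = None

    manifest = {
        "seed": config.seed,
        "n_perm": config.n_perm,
        "exclusions": list(config.exclusions),
        "inputs": reports,
        "counts": {
            "curves": len(curves), "use_calls": len(use_calls), "fits": len(fits),
            "q10s": len(q10s), "trait_table_rows": len(trait_table),
            "k_tests": len(phylosig), "mantel_tests": len(mantel_table),
        },
    }
    return PipelineResult(tree=tree, fits=fits, use_calls=use_calls, q10s=q10s,
                          co2_summaries=co2_summaries, trait_table=trait_table,
                          phylosignal=phylosig, mantel=mantel_table,
                          correlations=correlations, pca=pca_result,
                          manifest=manifest, ground_truth=ground_truth)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "fits.tsv": (result.fits, False),
        "use_calls.tsv": (result.use_calls, False),
        "q10.tsv": (result.q10s, False),
        "co2_summaries.tsv": (result.co2_summaries, False),
        "trait_table.tsv": (result.trait_table, True),
        "phylosignal.tsv": (result.phylosignal, False),
        "mantel.tsv": (result.mantel, False),
        "correlations.tsv": (result.correlations, False),
    }
    if result.pca is not None:
        files["pca_scores.tsv"] = (result.pca.scores, True)
        files["pca_variance.tsv"] = (pd.DataFrame({
            "component": [f"PC{i+1}" for i in range(len(result.pca.percent_variance))],
            "percent_variance": result.pca.percent_variance}), False)
    for name, (df, with_index) in files.items():
        _write_tsv(df, out / name, index=with_index)
    (out / "tree.nwk").write_text(
        result.tree.as_string(schema="newick", suppress_rooting=True))

    hashes = {}
    for name in list(files) + ["tree.nwk"]:
        hashes[name] = hashlib.sha256((out / name).read_bytes()).hexdigest()
    result.manifest["files"] = hashes
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True, default=str) + "\n")
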