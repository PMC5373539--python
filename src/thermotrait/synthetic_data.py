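"""Seeded generators for trees, trait architectures, plate and CO2 data.

The generators emulate the statistical structure of a litter-bacteria
physiology study: a pure-birth (Yule) phylogeny over the isolates, a
heritable (Brownian-motion) or non-heritable (white-noise) architecture for
the per-isolate growth-rate trait, 31-substrate EcoPlate time series in
triplicate at three temperatures, and microcosm headspace CO2 series whose
rates scale across temperature as ``q10 ** (dT / 10)``.  Every dataset is
returned together with its ground truth so downstream fitting and testing
stages have a parameter-recovery surface.

All randomness flows from a single integer seed through named substreams, so
identical configurations yield identical outputs byte for byte.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .phylo_signal import PhyloTree, vcv_from_tree
from .plate_growth import CONTROL_SUBSTRATE, gompertz

__all__ = [
    "ECOPLATE_SUBSTRATES",
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_white_noise_traits",
    "simulate_plate_experiment",
    "simulate_co2_experiment",
    "simulate_study",
]

#: The 31 carbon substrates of a Biolog EcoPlate.
ECOPLATE_SUBSTRATES = (
    "Phenylethylamine", "Putrescine",
    "L-Arginine", "L-Asparagine", "L-Phenylalanine", "L-Serine", "L-Threonine",
    "D-Cellobiose", "D-Galactonic Acid g-Lactone", "D-Mannitol", "D-Xylose",
    "D,L-a-Glycerol Phosphate", "Glucose-1-Phosphate", "i-Erythritol",
    "N-Acetyl-D-Glucosamine", "a-D-Lactose", "b-Methyl-D-Glucoside",
    "D-Galacturonic Acid", "D-Glucosaminic Acid", "D-Malic Acid",
    "Glycyl-L-Glutamic Acid", "Itaconic Acid", "Pyruvic Acid Methyl Ester",
    "a-Ketobutyric Acid", "g-Hydroxybutyric Acid",
    "2-Hydroxy Benzoic Acid", "4-Hydroxy Benzoic Acid",
    "Glycogen", "Tween 40", "Tween 80", "a-Cyclodextrin",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and noise model for the synthetic experiments.

    Defaults mirror the emulated study: 16 isolates assayed on 31 substrates
    in triplicate at 18/22/26 degC, plates read on days 0,1,2,3,5,7,10 and
    microcosm headspace CO2 on days 1,2,3,6,8,10, with rates scaling across
    temperature by ``true_q10 ** (dT/10)``.
    """

    n_taxa: int = 16
    birth_rate: float = 1.0
    #: BM diffusion rate of the log growth-rate trait.  On a unit-depth Yule
    #: tree this yields ~10-fold rate differences between extreme isolates,
    #: the spread observed between fast and slow litter bacteria.
    sigma2_bm: float = 0.3
    noise_sd_od: float = 0.02  # additive OD590 measurement noise (OD units)
    temperatures: tuple[float, ...] = (18.0, 22.0, 26.0)
    true_q10: float = 2.0
    n_replicates: int = 3
    sampling_days: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0)
    co2_sampling_days: tuple[float, ...] = (1.0, 2.0, 3.0, 6.0, 8.0, 10.0)
    seed: int = 0
    # plate forward-model settings
    n_substrates: int = 31
    use_probability: float = 0.4  # chance an isolate can use a given substrate
    base_mu_max: float = 0.8  # OD/day at the coldest temperature
    base_co2_rate: float = 1100.0  # ppm/day at the coldest temperature
    noise_frac_co2: float = 0.05  # relative noise on per-interval CO2 increments
    #: per-isolate spread of log Q10 around true_q10 (isolates differ in
    #: temperature sensitivity; ~2x between extremes at the default)
    q10_log_sd: float = 0.2
    ambient_baseline_ppm: float = 400.0
    #: optional per-temperature rate multipliers overriding Q10 scaling, to
    #: model non-monotone responses (e.g. a mid-temperature activity peak)
    temperature_multipliers: Mapping[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        for name in ("birth_rate", "sigma2_bm", "true_q10", "base_mu_max",
                     "base_co2_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_od < 0 or self.noise_frac_co2 < 0 or self.q10_log_sd < 0:
            raise ValueError("noise magnitudes must be nonnegative")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0.0 <= self.use_probability <= 1.0):
            raise ValueError("use_probability must be in [0, 1]")
        if not (1 <= self.n_substrates <= len(ECOPLATE_SUBSTRATES)):
            raise ValueError(
                f"n_substrates must be in [1, {len(ECOPLATE_SUBSTRATES)}]")

    @property
    def substrates(self) -> tuple[str, ...]:
        return ECOPLATE_SUBSTRATES[: self.n_substrates]


@dataclass
class GroundTruth:
    """True parameters behind a simulated dataset, for recovery tests."""

    tree: PhyloTree
    trait_model: str  # "bm" or "white-noise"
    trait_values: pd.Series  # per-isolate log growth-rate factor
    q10_per_isolate: pd.Series
    used: dict[tuple[str, str], bool] = field(default_factory=dict)
    gompertz_params: dict[tuple[str, str, float], tuple[float, float, float, float]] = \
        field(default_factory=dict)
    co2_rates: dict[tuple[str, float], float] = field(default_factory=dict)


def _substream(seed: int, label: str) -> np.random.Generator:
    # crc32 keyed substreams: stable across processes (unlike builtin hash)
    key = zlib.crc32(label.encode("utf8")) % (2 ** 31)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def simulate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree with ``n_taxa`` extant tips.

    The process is stopped at the n-th birth; every pendant edge is then
    extended by the waiting time to the next speciation event so that all
    terminal branch lengths are strictly positive (ultrametricity preserved).
    Tips are relabeled iso01..isoNN deterministically.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    from dendropy.model import birthdeath

    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_taxa, rng=rng)
    extra = rng.expovariate(n_taxa * birth_rate)
    width = len(str(n_taxa))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
        leaf.taxon.label = f"iso{i:0{width}d}"
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def simulate_bm_traits(tree: PhyloTree, sigma2: float, root_value: float = 0.0,
                       seed: int = 0) -> pd.Series:
    """Brownian-motion tip traits: MVN(root_value, sigma2 * VCV(tree))."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    V = vcv_from_tree(tree)
    L = np.linalg.cholesky(sigma2 * V.to_numpy())
    rng = np.random.default_rng(seed)
    z = root_value + L @ rng.standard_normal(V.shape[0])
    return pd.Series(z, index=V.index)


def simulate_white_noise_traits(n: int | list[str], mean: float = 0.0, sd: float = 1.0,
                                seed: int = 0) -> pd.Series:
    """i.i.d. normal traits -- the no-phylogenetic-signal regime.

    ``n`` may be a count (labels iso01..isoNN) or an explicit label list.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if isinstance(n, int):
        if n < 1:
            raise ValueError("n must be >= 1")
        width = len(str(n))
        labels = [f"iso{i:0{width}d}" for i in range(1, n + 1)]
    else:
        labels = list(n)
        if len(labels) < 1:
            raise ValueError("need at least one label")
    rng = np.random.default_rng(seed)
    return pd.Series(mean + sd * rng.standard_normal(len(labels)), index=labels)


def _trait_architecture(tree: PhyloTree, config: SimulationConfig, mode: str,
                        stream: str) -> pd.Series:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seed = int(_substream(config.seed, stream).integers(2 ** 31))
    if mode == "bm":
        return simulate_bm_traits(tree, config.sigma2_bm, 0.0, seed=seed)
    if mode in ("white", "white-noise"):
        depth = float(np.mean(np.diag(vcv_from_tree(tree))))
        sd = float(np.sqrt(config.sigma2_bm * depth))
        return simulate_white_noise_traits(labels, 0.0, sd, seed=seed)
    raise ValueError(f"unknown trait architecture: {mode!r}")


def _temperature_factor(config: SimulationConfig, q10: float, temp: float) -> float:
    if config.temperature_multipliers is not None:
        return float(config.temperature_multipliers[temp])
    t_cold = min(config.temperatures)
    return float(q10 ** ((temp - t_cold) / 10.0))


def _per_isolate_q10(labels: list[str], config: SimulationConfig,
                     mode: str, tree: PhyloTree) -> pd.Series:
    if config.q10_log_sd == 0.0:
        return pd.Series(config.true_q10, index=labels)
    seed = int(_substream(config.seed, "q10-trait").integers(2 ** 31))
    if mode == "bm":
        depth = float(np.mean(np.diag(vcv_from_tree(tree))))
        eta = simulate_bm_traits(tree, config.q10_log_sd ** 2 / depth, 0.0, seed=seed)
    else:
        eta = simulate_white_noise_traits(labels, 0.0, config.q10_log_sd, seed=seed)
    return config.true_q10 * np.exp(eta)


def simulate_plate_experiment(config: SimulationConfig, ground_truth_mode: str = "bm",
                              tree: PhyloTree | None = None,
                              q10_mode: str = "white",
                              ) -> tuple[pd.DataFrame, GroundTruth]:
    """Forward-simulate EcoPlate OD590/OD750 time series.

    Each isolate carries a log growth-rate trait (architecture per
    ``ground_truth_mode``); which substrates an isolate can use follows a
    thresholded per-substrate liability with the same architecture, so in
    "bm" mode both growth rates and use profiles are phylogenetically
    heritable, as in real litter communities.  Usable combinations get
    Gompertz parameters whose rate scales across temperature by the
    isolate's Q10; unusable combinations and the carbon-free control wells
    stay at baseline.  Additive Gaussian OD noise is truncated at zero.

    Returns the long-format plate table (columns isolate, substrate,
    temperature_c, replicate, day, od590, od750) and the ground truth.
    """
    if tree is None:
        tree_seed = int(_substream(config.seed, "tree").integers(2 ** 31))
        tree = simulate_tree(config.n_taxa, config.birth_rate, seed=tree_seed)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    z = _trait_architecture(tree, config, ground_truth_mode, "plate-trait")
    q10s = _per_isolate_q10(labels, config, q10_mode, tree)

    rng = _substream(config.seed, "plate")
    truth = GroundTruth(tree=tree,
                        trait_model={"bm": "bm"}.get(ground_truth_mode, "white-noise"),
                        trait_values=z, q10_per_isolate=q10s)

    subst_factor = {s: float(np.exp(rng.normal(0.0, 0.3)))
                    for s in config.substrates}

    # substrate-use architecture: thresholded liability, heritable in BM mode
    depth = float(np.mean(np.diag(vcv_from_tree(tree))))
    cutoff = float(stats.norm.ppf(1.0 - config.use_probability)) * np.sqrt(depth)
    use_matrix: dict[str, pd.Series] = {}
    for s in config.substrates:
        s_seed = int(rng.integers(2 ** 31))
        if ground_truth_mode == "bm":
            liab = simulate_bm_traits(tree, 1.0, 0.0, seed=s_seed)
        else:
            liab = pd.Series(
                np.sqrt(depth) * np.random.default_rng(s_seed).standard_normal(len(labels)),
                index=labels)
        use_matrix[s] = liab > cutoff

    days = np.asarray(config.sampling_days, dtype=float)
    rows: list[tuple] = []
    for iso in labels:
        for s in list(config.substrates) + [CONTROL_SUBSTRATE]:
            is_control = s == CONTROL_SUBSTRATE
            used = (not is_control) and bool(use_matrix[s][iso])
            if not is_control:
                truth.used[(iso, s)] = used
            A = float(rng.uniform(0.6, 1.2))
            y0 = float(rng.uniform(0.03, 0.07))
            lam_cold = float(rng.uniform(0.5, 1.5))
            for temp in config.temperatures:
                f = _temperature_factor(config, float(q10s[iso]), temp)
                mu = config.base_mu_max * float(np.exp(z[iso])) * subst_factor.get(s, 1.0) * f
                lam = lam_cold / f
                if used:
                    truth.gompertz_params[(iso, s, temp)] = (A, mu, lam, y0)
                    clean = gompertz(days, A, mu, lam, y0)
                else:
                    clean = np.full_like(days, y0)
                for rep in range(1, config.n_replicates + 1):
                    od590 = np.maximum(
                        clean + rng.normal(0.0, config.noise_sd_od, len(days))
                        if config.noise_sd_od > 0 else clean, 0.0)
                    od750 = np.maximum(
                        0.08 + 0.5 * (clean - y0)
                        + (rng.normal(0.0, config.noise_sd_od / 2, len(days))
                           if config.noise_sd_od > 0 else 0.0), 0.0)
                    for d, v590, v750 in zip(days, od590, od750):
                        rows.append((iso, s, temp, rep, d, float(v590), float(v750)))

    table = pd.DataFrame(rows, columns=[
        "isolate", "substrate", "temperature_c", "replicate", "day", "od590", "od750"])
    return table, truth


def simulate_co2_experiment(config: SimulationConfig, ground_truth_mode: str = "bm",
                            tree: PhyloTree | None = None,
                            q10_mode: str = "white",
                            ) -> tuple[pd.DataFrame, GroundTruth]:
    """Forward-simulate microcosm headspace CO2 measurements.

    Each isolate respires at ``base_co2_rate * exp(trait)`` ppm/day at the
    coldest temperature, scaled by its Q10 at warmer ones.  Microcosms are
    vented to ambient between samplings, so each raw measurement is
    ambient + rate * interval (with optional relative noise); cumulating the
    above-ambient parts recovers a nondecreasing series.

    Returns the long-format table (isolate, temperature_c, replicate, day,
    co2_ppm) and the ground truth.
    """
    if tree is None:
        tree_seed = int(_substream(config.seed, "tree").integers(2 ** 31))
        tree = simulate_tree(config.n_taxa, config.birth_rate, seed=tree_seed)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    w = _trait_architecture(tree, config, ground_truth_mode, "co2-trait")
    q10s = _per_isolate_q10(labels, config, q10_mode, tree)

    rng = _substream(config.seed, "co2")
    truth = GroundTruth(tree=tree,
                        trait_model={"bm": "bm"}.get(ground_truth_mode, "white-noise"),
                        trait_values=w, q10_per_isolate=q10s)

    days = np.asarray(config.co2_sampling_days, dtype=float)
    intervals = np.diff(np.concatenate([[0.0], days]))
    rows: list[tuple] = []
    for iso in labels:
        for temp in config.temperatures:
            f = _temperature_factor(config, float(q10s[iso]), temp)
            rate = config.base_co2_rate * float(np.exp(w[iso])) * f
            truth.co2_rates[(iso, temp)] = rate
            for rep in range(1, config.n_replicates + 1):
                inc = rate * intervals
                if config.noise_frac_co2 > 0:
                    inc = inc * (1.0 + rng.normal(0.0, config.noise_frac_co2, len(inc)))
                measured = np.maximum(config.ambient_baseline_ppm + np.maximum(inc, 0.0), 0.0)
                for d, ppm in zip(days, measured):
                    rows.append((iso, temp, rep, d, float(ppm)))

    table = pd.DataFrame(rows, columns=[
        "isolate", "temperature_c", "replicate", "day", "co2_ppm"])
    return table, truth


def simulate_study(config: SimulationConfig, functional_mode: str = "bm",
                   q10_mode: str = "white") -> dict:
    """One coherent synthetic study: a shared tree, plate data and CO2 data.

    ``functional_mode`` sets the architecture of the growth/respiration
    traits ("bm" = phylogenetically heritable); ``q10_mode`` sets the
    architecture of the per-isolate temperature sensitivities (requires
    ``config.q10_log_sd > 0`` to produce any variation).
    """
    tree_seed = int(_substream(config.seed, "tree").integers(2 ** 31))
    tree = simulate_tree(config.n_taxa, config.birth_rate, seed=tree_seed)
    plate, plate_truth = simulate_plate_experiment(
        config, ground_truth_mode=functional_mode, tree=tree, q10_mode=q10_mode)
    co2, co2_truth = simulate_co2_experiment(
        config, ground_truth_mode=functional_mode, tree=tree, q10_mode=q10_mode)
    return {"tree": tree, "plate": plate, "co2": co2,
            "plate_truth": plate_truth, "co2_truth": co2_truth}
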