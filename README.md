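# thermotrait

Tools for asking whether the **functional traits** of leaf-litter bacteria
(which carbon substrates they use, how fast they grow on them, how much CO₂
they respire from litter) and their **response traits** (how sensitive those
rates are to temperature) are phylogenetically conserved.

The package re-implements, as a tested and reusable pipeline, the analysis
chain used in community-level physiological profiling studies of litter
bacteria: Biolog-EcoPlate growth curves at several temperatures, microcosm
CO₂ production, Q₁₀ temperature sensitivities, and permutation tests for
phylogenetic signal. A seeded synthetic-data generator emulates the full
study design — 16 isolates on a phylogeny, 31 substrates in triplicate at
18/22/26 °C, headspace CO₂ time series — so every stage can be verified
against known ground truth without any external data.

## The models and statistics

**Growth curves.** Replicate-averaged OD₅₉₀ trajectories are fit with the
modified Gompertz model (Zwietering parameterization)

    y(t) = A · exp{ −exp[ μmax·e/A · (λ − t) + 1 ] } + y₀

where *A* is the carrying capacity, *μmax* the maximum growth rate (the
steepest slope of the fitted sigmoid), *λ* the lag time and *y₀* the initial
density. A substrate counts as **utilized** when the triplicate-mean OD₅₉₀
after 10 days is ≥ 0.30, a threshold above the carbon-free control wells.

**Temperature sensitivity.** Q₁₀ is the factor by which a rate changes per
10 °C of warming, computed from the two extreme temperatures:

    Q10 = (rate_26 / rate_18)^(10 / (26 − 18))

For litter decomposition the rate is measured inversely, as the time for a
microcosm to accumulate 5000 ppm of headspace CO₂, giving the equivalent
form `Q10 = (t_18 / t_26)^(10/8)`.

**Phylogenetic signal.** Blomberg's K compares the observed trait variance
to the variance expected under Brownian motion on the tree (K ≈ 1 under BM,
K → 0 with no signal); significance comes from 999 permutations of trait
values across tips. Substrate-use profiles are compared to the phylogeny
with Mantel tests between the patristic distance matrix and Euclidean trait
distance matrices, again with 999 permutations. Both tests use the add-one
rule `p = (1 + #{null ≥ observed}) / (1 + n_perm)`.

## Worked example

Run the whole pipeline on a simulated study in which growth physiology is
phylogenetically heritable (Brownian motion) but per-isolate temperature
sensitivity is not (white noise):

```python
import thermotrait as tt

config = tt.RunConfig(simulation=tt.SimulationConfig(seed=5), seed=5)
result = tt.run_pipeline(config)
print(result.phylosignal[["trait", "statistic", "p", "n_used"]].round(3))
print(result.mantel[["trait", "statistic", "p"]].round(3))
```

prints

```
               trait  statistic      p  n_used
0        mean_mu_max      0.135  0.343      16
1         mean_od590      0.291  0.106      16
2           richness      0.645  0.011      16
3     cumulative_co2      0.131  0.295      16
4         q10_mu_max      0.008  0.920      16
5          q10_od590      0.018  0.855      16
6  q10_decomposition      0.008  0.942      14

           trait  statistic      p
0  substrate_use      0.847  0.001
1     mean_od590      0.824  0.001
2    mean_mu_max      0.233  0.062
3     q10_mu_max     -0.413  1.000
4      q10_od590     -0.390  1.000
```

Reading this: the substrate-use profile tracks the phylogeny strongly
(Mantel r = 0.85, p = 0.001) and substrate-use richness carries significant
Blomberg-K signal (K = 0.65, p = 0.011) — closely related isolates use
similar carbon sources. The three Q₁₀ response traits show no signal
(K ≤ 0.02, p ≥ 0.85), exactly the architecture the data were simulated
with. `q10_decomposition` uses 14 of 16 tips because two isolates never
reached the 5000 ppm CO₂ threshold at 18 °C, which makes their
decomposition Q₁₀ undefined rather than zero.

The same analysis runs from files (`tree.nwk`, `plate.csv`, `co2.csv`;
schemas documented in `thermotrait.pipeline_io`) via the CLI:

```bash
thermotrait simulate --n-taxa 16 --seed 5 --out-dir study/
thermotrait run --simulate --seed 5 --out-dir results_run/
thermotrait report results_run/
```

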