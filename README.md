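# seedshift

Trait-based metacommunity simulation of annual plants on a warming
temperature gradient.

`seedshift` asks a question relevant to anyone forecasting biodiversity
change: **how much do assumptions about dispersal — and its life-history
costs — change model predictions of extinction risk under climate
change?**  It simulates a community of 200 annual plant species competing
along a 6 °C / 50 km temperature (elevation) gradient while the whole
gradient warms sigmoidally by 3 °C over 150 years, and compares three
assumptions about seed dispersal:

* **uniform** — every species disperses identically (the usual modelling
  shortcut);
* **variable** — dispersal distance varies among species with seed mass
  but costs nothing else (neutral variation);
* **trade-off** — the seed-mass/seed-number trade-off: species with
  heavier seeds disperse less far and produce fewer seeds, but each seed
  germinates more reliably and yields a larger seedling.

## Model

Each species *i* carries a thermal optimum `T_opt,i` and a seed mass
`SM_i` (mg).  Within a 120-day growing season, biomass follows discrete
Lotka–Volterra competition with Gaussian temperature-dependent growth,

    r_i(T) = r_max · exp(−(T − T_opt,i)² / (2 σ_opt²)),
    B_i(t+1) = B_i + r_i (1 − B_i/K_i − Σ_{j≠i} α_ij B_j/K_j) B_i − m B_i,

with `K_i ∝ r_i`, `α_ii = 1` and a single interspecific coefficient
`α_ij < 1`.  At season's end adults set seed and die; seeds move between
patches deterministically through a leptokurtic two-dimensional
exponential-power kernel,

    P(d, β) = c / (2π β² Γ(2/c)) · exp(−(d/β)^c),   c = 0.5,

whose mean distance scales with seed mass as `δ = a · SM^−0.13`
(`a = 600` m, so a 1 mg seed travels 600 m on average).  A key emergent
property — the *kernel effect* — is that a shorter mean distance also
raises the probability of deposition near the parent, handing
short-dispersing (large-seeded) species a pre-emptive local advantage.
Landscape boundaries are open; a dynamically extrapolated downslope
species pool supplies warmer-adapted immigrants so the warm edge never
empties.  Response variables (richness, inverse-Simpson α/β/γ diversity
with β = γ/α, Jaccard dissimilarity, colonisation/exclusion events,
abundance-weighted geometric-mean seed mass, and the climate-tracking lag
of the 40 warmest-adapted species) are computed over *native* species
only — those present at equilibrium after a stable-climate run-up.

See `docs/methods.md` for assumptions, parameter defaults and their
calibration, numerical choices, and known limitations.

## Worked example

Run the trade-off scenario at the strongest competition level for three
replicates:

```bash
seedshift simulate --scenario tradeoff --alpha 0.5 --replicates 3 --seed 7 --out demo/
```

prints

```
mean pct extinctions: 21.4%
mean pct gamma-diversity change: -23.0%
wrote demo/summary.csv
```

meaning that, averaged over the three replicates, 21.4 % of the native
species (those present at the pre-warming equilibrium) were regionally
extinct after the 3 °C warming plus a 50-year settling window, and
regional inverse-Simpson diversity fell by 23 %.  `summary.csv` holds one
row per replicate with the full set of response variables for the stable
and post-warming phases; `metadata.json` records the fully resolved
configuration so any run can be repeated bit-identically.

The experiment grids behind the scenario table and the seed-mass
factorial are available as presets:

```bash
seedshift sweep table1_baseline  --seed 42 --out sweep_out/   # 3 scenarios x alpha {0, 0.1, 0.3, 0.5}
seedshift sweep fig2_sm_factorial --seed 42 --out factorial/  # SM mean x SD grid at alpha = 0.5
```

Everything is equally accessible from Python:

```python
from seedshift import RunConfig, run_replicates

df = run_replicates(RunConfig(scenario="variable", alpha_inter=0.5, n_replicates=30, seed=1))
print(df["pct_change_richness"].mean())
```

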