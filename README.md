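# methanotherm

Tools for quantifying the **temperature sensitivity of methanogenesis** in
anoxic soil incubations, aimed at microbial ecologists and biogeochemists who
run temperature-ladder bottle experiments on wetland, peat or paddy soils.

Cold wetlands are major methane sources, and how their CH₄ production responds
to warming depends on *which* methanogens are active: aceticlastic communities
(acetate → CH₄ + CO₂) tend to respond much more steeply to temperature than
hydrogenotrophic ones (CO₂ + H₂ → CH₄). This package implements the complete
quantitative chain used to diagnose that behaviour:

1. **Rate extraction** — the maximal production rate *P* of CH₄ or CO₂ is the
   largest sliding-window least-squares slope of the cumulative headspace
   curve; the lag is the time-axis intercept of the tangent through that
   window.
2. **Arrhenius analysis** — temperature dependence is characterized by

   ln *P* = *E*·(−1/*RT*) + *M*

   with *T* the absolute temperature (K), *R* the Boltzmann constant
   (8.623 × 10⁻⁵ eV K⁻¹) and *E* the apparent activation energy (eV).
   A community whose composition shifts with temperature shows **two
   regimes**; `thermo.fit_segmented` finds the best temperature cut by
   exhaustive search (two independent OLS lines, minimum pooled RSS) and
   `thermo.select_model` arbitrates one-vs-two regimes with an
   extra-sum-of-squares F-test. Rates can be normalized by the peak *mcrA*
   gene abundance per temperature to remove the enzyme (biomass) factor.
3. **Isotope pathway diagnosis** — the apparent fractionation factor
   α_app = (δ¹³C-CO₂ + 10³)/(δ¹³C-CH₄ + 10³) classifies the dominant
   pathway: < 1.03 aceticlastic-dominated, ≥ 1.04 mixed/hydrogenotrophic.
4. **Community profiling** — T-RFLP percent abundances with the 1 % minor-peak
   filter, in silico TaqI (T^CGA) terminal-fragment prediction from the
   labeled-primer end, fragment→taxon assignment (±1 bp), Good's coverage and
   analytic rarefaction of clone libraries.
5. **Synthetic experiments** — `synthetic.simulate_dataset` generates a full
   temperature-ladder incubation (gas curves, qPCR table, δ¹³C series, T-RFLP
   profiles, clone libraries) with known ground truth, so every stage is
   testable end to end.

## Worked example

Simulate the default experiment (10–35 °C in 5 °C steps, 81 days, triplicate
bottles) and run the full analysis:

```sh
methanotherm simulate --seed 42 --out demo/data
methanotherm report --out demo/out \
    --gas demo/data/gas.csv --qpcr demo/data/qpcr.csv \
    --isotopes demo/data/isotopes.csv --peaks demo/data/trflp.tsv \
    --libraries demo/data/libraries.tsv
```

`demo/out/summary.json` then contains (seed 42):

```
ch4 selected: segmented      break after 15 °C, E_low 3.899 eV, E_high 1.044 eV
co2 selected: single         E 0.637 eV
pathway: 15 °C aceticlastic-dominated, 25/35 °C mixed/hydrogenotrophic-enriched
coverage: 94 / 97 / 100 % (libraries at 15 / 25 / 35 °C, day 49)
```

Read: CH₄ production is far more temperature-sensitive below the community
shift (≈3.9 eV) than above it (≈1.0 eV), while CO₂ production follows a single
modest regime (≈0.6 eV) — and the isotopes show the methanogenic pathway
moving from aceticlastic toward a hydrogenotrophic mixture as it warms, in
step with the kinetic break. The generating truth for this run (E_low 3.9,
E_high 1.1, break 17.5 °C, E_CO₂ 0.6 eV) is in `demo/data/truth.json`.

As a library:

```python
from methanotherm import kinetics, thermo
from methanotherm.synthetic import build_default_scenario, simulate_gas

cfg = build_default_scenario()
gas = simulate_gas(cfg, seed=1)
rates = kinetics.rates_by_temperature(gas, "ch4", window_points=3)
fit = thermo.fit_segmented(thermo.transform_rates(rates))
print(fit.break_after_temperature_C, fit.low.E, fit.high.E)
```

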