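# solvitc

Analysis tools for binding and folding equilibria in which the solvent is an
explicit thermodynamic participant. The central relationship is

```
dG_standard = -R*T*ln(K) - [AB] * dG_solv
```

where `K` is the molar-based equilibrium quotient, `[AB]` the equilibrium
complex concentration, `dG_standard` the standard-state free energy and
`dG_solv` the change in solvation free energy per molar of complex formed.
When `dG_solv != 0` the equilibrium quotient is *not* constant: it shifts
with product concentration, which is measurable by running isothermal
titration calorimetry (ITC) at several concentrations and regressing
`-R*T*ln(K)` on `[AB]` (slope = `dG_solv`, intercept = `dG_standard`).

## What is included

- `solvitc.thermo` — constants, unit helpers, and the algebraic forms of
  the governing equation.
- `solvitc.solver` — bracketed root solving for the equilibrium complex
  concentration `Z` from total concentrations, plus the closed-form
  classical (constant-K) solution used as an oracle.
- `solvitc.titration` — per-injection titration simulation (constant
  increment or displacement dilution), the `K` trajectory and simulated
  heats, and the rule pairing a fitted `K` with the complex concentration
  at the last pre-equivalence injection.
- `solvitc.fitting` — classical one-site `(K, dH, n)` least-squares fitting
  (emulating instrument software) and a direct fit of the
  solvation-corrected model.
- `solvitc.regression` — characteristic-plot regression returning
  `dG_solv`, `dG_standard`, standard errors and `r^2`; optional
  inverse-variance weighting from replicate dispersions.
- `solvitc.vanthoff` — per-strand base-unstacking free energies, the
  stacked-fraction correction `dG = dG_itc - f * dG_un`, and van't Hoff
  fits in `ln K` vs `1/T` or `dG` vs `T` form.
- `solvitc.folding` — two-state folding fraction under the governing
  equation, two-basis CD spectrum prediction, and a concentration-
  independence statistic for dilution series at constant
  concentration x pathlength.
- `solvitc.synth` — seeded generators for noisy heats tables, `K`-series,
  and CD dilution series.
- `solvitc.io` / `solvitc.cli` — delimited-text table schemas, YAML/JSON
  run configuration, and the command-line interface.

## CLI

```sh
solvitc simulate      --config run.yaml --out trace.csv
solvitc fit-itc       --heats heats.csv --config run.yaml --out fit.csv
solvitc fit-solvation --in k_table.csv --temp-C 25 [--weighting inverse_variance]
solvitc vant-hoff     --in gibbs_table.csv --mode lnK_vs_invT
solvitc fold          --dg0 -0.8 --dgs 0 --ptotal-mg-ml 5
solvitc synth         itc|kseries|cd --seed 3 --out outdir/
```

A run configuration looks like:

```yaml
conditions: {temperature_C: 25}
params: {dG_standard: -9.30, dG_solv: 4000}
schedule:
  n_injections: 28
  injection_volume_uL: 10
  cell_volume_mL: 1.45
  syringe_conc_M: 2.0e-3
  cell_conc_initial_M: 2.0e-4
dH_bind: -47
```

Table schemas: K tables carry `temperature_C, complex_conc_M, K[, K_sd]`;
heats tables carry `injection, volume_uL, heat_kcal|heat_ucal`; traces carry
`injection, Xt_M, Mt_M, molar_ratio, Z_M, K, q_kcal, q_norm_kcal_per_mol`.

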