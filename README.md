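# cdsorb

Thermo-kinetic analysis of water sorption on β-cyclodextrin (β-CD), the
cyclic seven-glucose host used throughout pharmaceutical formulation. The
strength of the water–host interaction controls how guest molecules displace
water from the β-CD cavity, and it can be quantified from four routine
measurements. `cdsorb` implements the full analysis chain for each of them,
plus a synthetic-data generator with known ground truth so every stage can be
validated by parameter recovery:

1. **Isosteric heat of adsorption** from vapor-sorption isotherms at two or
   more temperatures, via the Clausius–Clapeyron relation at fixed loading q:

       Q(q) = −R · d(ln P) / d(1/T) |_q

2. **Activation energy of adsorption** from staged-humidity uptake traces.
   Within a stage at constant vapor pressure P_i the uptake follows
   dq/dt = k·P_i·(1 − P_i(q)/P_i); the initial-rate method (OLS slope over
   the first 10 samples of a stage) divided by the pressure step P_i − P_{i−1}
   gives the stage rate constant k, and ln k vs 1/T gives E_a.

3. **Activation energy of desorption** from thermogravimetry at several
   heating rates β, by the model-free Friedman isoconversional method: at
   each fixed conversion α, the slope of ln(dα/dt) vs 1/T across heating
   rates gives E(α) without assuming a reaction model f(α).

4. **Molar dehydration enthalpy** from DSC: baseline-correct the endotherm,
   integrate |heat flow| over time, divide by sample mass, and convert with
   the water mass fraction w: ΔH = (J/g)·M_water/(1000·w) in kJ per mol of
   water. The TG side also yields the hydration stoichiometry
   n = (w/(1−w))·(M_βCD/M_water) mol water per mol host.

The analyses are exposed statsmodels-style — a model object built from data
whose `fit()` returns a results object with the estimates and a `summary()` —
plus plain functions for the smaller operations, a CSV interchange format for
instrument traces, and a `cdsorb` command-line tool.

## Worked example

Fit the Arrhenius model to the reference uptake rate constants (mmol min⁻¹
Pa⁻¹ at 283, 298 and 313 K):

```bash
$ cdsorb arrhenius --k 10.64e-5,9.12e-5,7.88e-5 --T 283,298,313
ln(rate) vs 1/T regression
--------------------------
n points            : 3
slope               : 886.3 K
activation energy   : 7.369 kJ/mol
ln(pre-exponential) : -12.28
pre-exponential     : 4.648e-06
R^2                 : 0.999814
```

The rate constant *falls* with temperature (the raw slope is positive), so
the apparent activation energy is reported under the magnitude convention,
|slope|·R ≈ 7.4 kJ/mol — adsorption of water on β-CD is nearly barrierless,
while desorption (below) costs 37–55 kJ/mol.

The same from Python, together with the full synthetic pipeline:

```python
import cdsorb as cs

fit = cs.ArrheniusModel([283, 298, 313], [10.64e-5, 9.12e-5, 7.88e-5]).fit()
print(fit.activation_energy)        # 7.369 kJ/mol

bundle = cs.run_report(cs.default_config(seed=1, output_dir="demo_out"))
print(bundle.summary)
```

The report generates isotherms at 283/298/313 K, uptake staircases, and
TG/DSC ramps at 5/10/15/20 K min⁻¹ from the built-in ground-truth models,
then runs every analysis stage on them:

```json
{
  "isosteric_heat_min_kJ_per_mol": 44.679,
  "isosteric_heat_max_kJ_per_mol": 47.717,
  "hysteresis_area_283K": 0.5453,
  "Ea_adsorption_kJ_per_mol": 8.654,
  "water_fraction_mean": 0.12,
  "mol_water_per_mol_host": 8.59,
  "Ea_desorption_min_kJ_per_mol": 54.97,
  "Ea_desorption_max_kJ_per_mol": 55.02,
  "dH_mean_kJ_per_mol_water": 66.93
}
```

Reading the numbers: the isosteric heat sits in the mid-40s kJ/mol (well
above the ~20 kJ/mol of plain physisorption — hydrogen bonding and the cavity
effect at work); a 12.0% water content corresponds to 8.6 water molecules per
β-CD; the Friedman analysis recovers the generator's 55 kJ/mol desorption
barrier to within 0.1%; and the DSC pipeline recovers the generator's
67.5 kJ/mol dehydration enthalpy to within 1%. The recovered adsorption
E_a (8.65 vs 7.37 kJ/mol implied by the generating constants) carries the
initial-rate method's finite-sampling bias, discussed in
[docs/methods.md](docs/methods.md).

Other subcommands: `cdsorb simulate`, `cdsorb isosteric-heat a.csv b.csv c.csv`,
`cdsorb tg tg1.csv`, `cdsorb friedman tg*.csv`, `cdsorb dsc --trace d.csv`,
`cdsorb report --config cfg.yaml`. All traces use a plain CSV dialect with a
`#`-prefixed metadata header (see `cdsorb.io`).

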