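# Full synthetic study with instrument-like noise.
# Run with:  cdsorb report --config examples/config.yaml
seed: 1
output_dir: cdsorb_out
stages: [simulate, isotherms, uptake, tg, dsc]

parameters:
  n_points: 10          # samples per initial-rate fit
  smooth_window: 31     # Savitzky-Golay window (odd); widen for noisy TG data
  plateau_tol: 0.001    # dry-plateau criterion, fraction of final mass
  rh_window: [0.10, 0.60]
  # anchors: [440.0, 470.0]   # explicit DSC baseline anchors (K); default: auto

synthetic:
  temperatures_K: [283.0, 298.0, 313.0]
  heating_rates_K_per_min: [5.0, 10.0, 15.0, 20.0]
  # rh_grid / rh_stages default to 5-95% and 10-90% staircases
  k_rate: [1.064e-4, 9.12e-5, 7.88e-5]   # mmol min^-1 Pa^-1 per temperature
  sorption:
    q_m: 6.0            # monolayer capacity, mmol/g
    c0: 0.053           # GAB energy prefactor
    Q_c: 5.0            # van't Hoff heat of c(T), kJ/mol
    k_gab: 0.75
    hysteresis_factor: 1.2
  dehydration:
    E_true: 55.0        # kJ/mol
    lnA_true: 12.637    # ln(1/s)
    w_true: 0.12
    dH_true: 67.5       # kJ per mol water
    m_wet: 10.0         # mg
    baseline_slope: 0.02   # mW/K DSC drift
    noise_sd_mass: 0.003   # mg
    noise_sd_heat: 0.03    # mW
  noise:
    isotherm: 0.02      # mmol/g on generated isotherm loadings
    uptake: 0.0005      # mmol on generated uptake loadings

# To analyze measured traces instead, point the readers at CSV files:
# inputs:
#   tg: [data/tg_5K.csv, data/tg_10K.csv, data/tg_15K.csv, data/tg_20K.csv]
#   dsc: [data/dsc_5K.csv]

# Supplying rate constants directly fits the Arrhenius stage from them:
# arrhenius:
#   k: [10.64e-5, 9.12e-5, 7.88e-5]
#   T: [283, 298, 313]
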