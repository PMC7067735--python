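# Default pipeline parameterization: published species constants and
# economics, plus the synthetic demo landscape. Override any subset in a
# user config; unspecified values fall back to these.

seed: 42
output_dir: habfish_out

scenarios: [-10, 0, 11, 20, 30, 40, 48]
target_scenario: 11

synthetic:
  grid_size: 64
  cell_size: 250.0          # m
  autocorrelation_range: 1500.0   # m
  base_prevalence:
    perch: 0.30
    pikeperch: 0.15
  secchi_response:          # habitat log-odds per unit relative Secchi change
    perch: 2.0
    pikeperch: -3.0
  technique_noise: 0.3

species:
  perch:
    migration_distance: 10000.0   # m
    length_cutoff_cm: 20.0
    mean_weight_kg: 0.23
    depth_limit: 10.0             # m; shallow-water species
    length_proportion: 0.5875     # >20 cm share of >10 cm biomass
    biomass_factor: 1.7407407407407407   # (kg/ha) per CPUE unit, 9.4/5.4
    hpf:
      slope: 2.03
      slope_se: 0.69
      intercept: 9.39
      intercept_se: 1.27
      offset: 0.0
      n: 12
      p: 0.015
      r2: 0.46
  pikeperch:
    migration_distance: 15000.0
    length_cutoff_cm: 30.0
    mean_weight_kg: 0.51
    depth_limit: null
    length_proportion: 0.43333333333333335   # >30 cm share of >10 cm biomass
    biomass_factor: 4.0625               # 0.65/0.16
    hpf:
      slope: 0.05
      slope_se: 0.02
      intercept: 0.21
      intercept_se: 0.04
      offset: 0.02
      n: 12
      p: 0.013
      r2: 0.48

monitoring:
  n_sites: 11
  noise_sd:
    perch: 1.5
    pikeperch: 0.05
  exclude_sites: []

economics:
  published_rounding: true
  deflator: 1.1875          # 2002 -> 2018 price factor
  fx_sek_per_eur: 10.2567
  effort_perch: 505000.0    # gear days / yr
  effort_perch_ci: 124000.0 # 95% CI half-width
  effort_pike: 83000.0
  effort_pike_ci: 64000.0
  species:
    perch:
      wtp_sek_2002: 71.6
      wtp_eur: 8.29
      wpue_baseline: 0.8    # kg per fishing hour
    pikeperch:
      wtp_sek_2002: 153.0
      wtp_eur: 18.0
      wpue_baseline: 0.3
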