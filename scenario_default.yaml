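bee_species:
- taxon: bee_B1_specialist
  preferences:
    plant_P1: 0.92
    plant_P2: 0.05
    plant_P3: 0.02
    plant_P4: 0.01
  dirichlet_conc: 20.0
  mismatch_effect: -0.065
  mean_cells: 14.0
  nests_per_year: 5
  nesting_spread: 15.0
  length_measured: false
- taxon: bee_B2
  preferences:
    plant_P1: 0.64
    plant_P2: 0.26
    plant_P3: 0.07
    plant_P4: 0.03
  dirichlet_conc: 20.0
  mismatch_effect: -0.02
  mean_cells: 9.0
  nests_per_year: 7
  nesting_spread: 15.0
  length_measured: true
- taxon: bee_B3
  preferences:
    plant_P1: 0.44
    plant_P2: 0.29
    plant_P3: 0.17
    plant_P4: 0.06
    plant_P5: 0.04
  dirichlet_conc: 20.0
  mismatch_effect: -0.0098
  mean_cells: 8.0
  nests_per_year: 8
  nesting_spread: 15.0
  length_measured: true
- taxon: bee_B4
  preferences:
    plant_P1: 0.3
    plant_P2: 0.22
    plant_P3: 0.17
    plant_P4: 0.13
    plant_P5: 0.09
    plant_P6: 0.05
    plant_P7: 0.03
    plant_P8: 0.01
  dirichlet_conc: 20.0
  mismatch_effect: -0.0032
  mean_cells: 7.0
  nests_per_year: 17
  nesting_spread: 15.0
  length_measured: false
- taxon: bee_B5_generalist
  preferences:
    plant_P1: 0.125
    plant_P2: 0.125
    plant_P3: 0.125
    plant_P4: 0.125
    plant_P5: 0.125
    plant_P6: 0.125
    plant_P7: 0.125
    plant_P8: 0.125
  dirichlet_conc: 20.0
  mismatch_effect: -0.0003
  mean_cells: 6.0
  nests_per_year: 48
  nesting_spread: 15.0
  length_measured: false
plant_species:
- taxon: plant_P1
  peak_day: 75.0
  peak_sd: 12.0
  peak_abundance: 400.0
  year_shift_sd: 6.0
- taxon: plant_P2
  peak_day: 85.0
  peak_sd: 14.0
  peak_abundance: 300.0
  year_shift_sd: 6.0
- taxon: plant_P3
  peak_day: 95.0
  peak_sd: 13.0
  peak_abundance: 250.0
  year_shift_sd: 6.0
- taxon: plant_P4
  peak_day: 65.0
  peak_sd: 10.0
  peak_abundance: 150.0
  year_shift_sd: 6.0
- taxon: plant_P5
  peak_day: 105.0
  peak_sd: 15.0
  peak_abundance: 120.0
  year_shift_sd: 6.0
- taxon: plant_P6
  peak_day: 55.0
  peak_sd: 9.0
  peak_abundance: 80.0
  year_shift_sd: 6.0
- taxon: plant_P7
  peak_day: 115.0
  peak_sd: 12.0
  peak_abundance: 60.0
  year_shift_sd: 6.0
- taxon: plant_P8
  peak_day: 90.0
  peak_sd: 20.0
  peak_abundance: 50.0
  year_shift_sd: 6.0
n_years: 9
start_year: 2006
n_sites: 2
plots_per_site: 2
survey_interval: 7
season_length: 180
resource_threshold: 0.85
pollen_years: 3
pollen_grains: 300.0
pollen_pref_floor: 0.002
nest_year_offset_sd: 6.0
cell_noise_sd: 0.12
cell_year_sd: 0.06
cavity_intercept: 10.0
cavity_slope: 9.0
cavity_noise_sd: 4.0
mask_fraction: 0.6
seed: 0
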