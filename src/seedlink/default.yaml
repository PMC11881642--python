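# Default run configuration. Every key can be overridden by a user YAML/JSON
# file; unknown keys are rejected.
seed: 1
output_dir: seedlink_out
trait_matching: true

community:
  # trait tables; when set, they are read instead of generating a community
  plants_csv: null
  birds_csv: null
  # synthetic generator (log-normal traits, allometric abundances)
  n_plants: 50
  n_birds: 60
  fruit_diameter_log_mean: 2.302585092994046   # ln(10 mm)
  fruit_diameter_log_sd: 0.6
  plant_height_log_mean: 2.0794415416798357    # ln(8 m)
  plant_height_log_sd: 0.6
  fruit_mass_coeff: 0.000524                   # g per mm^3 (spherical fruit)
  body_mass_log_mean: 3.4011973816621555       # ln(30 g)
  body_mass_log_sd: 0.9
  gape_coeff: 4.0                              # mm at 1 g body mass
  gape_exp: 0.3333333333333333
  gape_log_noise_sd: 0.15
  wing_pointedness_log_mean: 3.2188758248682006  # ln(25)
  wing_pointedness_log_sd: 0.35
  plant_abundance_coeffs: [50.0, 0.75]         # fruits = c * fruit_mass^-beta
  bird_abundance_coeffs: [300.0, 0.75]         # individuals = c * body_mass^-beta

niche:
  s_levels: [1.5, 3.0, 5.0, 10.0, 20.0]
  skew_ratio: 3.0
  sigma_match: 0.666
  sigma_strata: 1.165
  s_exponent: 0.48

kernel:
  gpt_coeff: [12.0, 0.25]     # minutes = a_g * M^b_g
  speed_coeff: [360.0, 0.15]  # m/min   = a_v * M^b_v
  calibration: 0.004
  retention_cv: 0.5
  retention_max_factor: 3.5

events:
  n_per_plant: 100
  mode: uniform_per_plant     # or plant_abundance_weighted

grid:
  distance_start: 0
  distance_stop: 600
  distance_step: 10
  richness_levels: null       # null -> 0..n_plants
  iterations: 100
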