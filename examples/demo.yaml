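class_alpha: 0.05
conservation_alpha: 0.001
gmt_paths: {}
gsea_min_overlap: 15
gsea_n_perm: 300
gsea_weight: 1.0
inputs: {}
isa_cor_limit: 0.5
isa_max_iter: 100
isa_n_seeds: 200
isa_thr_col_grid:
- 1.0
- 1.5
- 2.0
- 2.5
- 3.0
isa_thr_row_grid:
- 1.0
- 1.5
- 2.0
- 2.5
- 3.0
isa_tol: 0.99
max_set_size: 500
min_set_size: 15
outdir: toxmod_demo
recovery_jaccard: 0.5
seed: 0
synthetic:
  beta0_mean: 7.0
  beta0_sd: 1.0
  beta2_sd: 0.1
  beta3_sd: 0.0
  disjoint_planted_genes: true
  missing_low_fraction: 0.2
  missing_low_settings:
  - PHH
  n_chemicals: 30
  n_genes:
    human: 2000
    rat: 2000
  n_pathways: 100
  noise_sd: 1.0
  pathway_size_range:
  - 15
  - 40
  planted_modules:
  - chemical_ids:
    - chem01
    - chem02
    - chem03
    - chem04
    - chem05
    - chem06
    effect_size: 2.0
    module_id: planted1
    pathway_ids:
    - PW001
    - PW002
    - PW003
    - PW004
    - PW005
    - PW006
    - PW007
    - PW008
    - PW009
    - PW010
    - PW011
    - PW012
    - PW013
    - PW014
    - PW015
    sign_per_pathway:
      PW001: -1
      PW002: 1
      PW003: -1
      PW004: -1
      PW005: -1
      PW006: -1
      PW007: 1
      PW008: 1
      PW009: 1
      PW010: 1
      PW011: -1
      PW012: -1
      PW013: 1
      PW014: -1
      PW015: -1
  - chemical_ids:
    - chem07
    - chem08
    - chem09
    - chem10
    - chem11
    - chem12
    effect_size: 2.0
    module_id: planted2
    pathway_ids:
    - PW016
    - PW017
    - PW018
    - PW019
    - PW020
    - PW021
    - PW022
    - PW023
    - PW024
    - PW025
    - PW026
    - PW027
    - PW028
    - PW029
    - PW030
    sign_per_pathway:
      PW016: -1
      PW017: 1
      PW018: -1
      PW019: -1
      PW020: -1
      PW021: -1
      PW022: 1
      PW023: 1
      PW024: 1
      PW025: 1
      PW026: -1
      PW027: -1
      PW028: 1
      PW029: 1
      PW030: -1
  - chemical_ids:
    - chem13
    - chem14
    - chem15
    - chem16
    - chem17
    - chem18
    effect_size: 2.0
    module_id: planted3
    pathway_ids:
    - PW031
    - PW032
    - PW033
    - PW034
    - PW035
    - PW036
    - PW037
    - PW038
    - PW039
    - PW040
    - PW041
    - PW042
    - PW043
    - PW044
    - PW045
    sign_per_pathway:
      PW031: -1
      PW032: -1
      PW033: -1
      PW034: 1
      PW035: 1
      PW036: 1
      PW037: 1
      PW038: 1
      PW039: -1
      PW040: -1
      PW041: -1
      PW042: -1
      PW043: 1
      PW044: -1
      PW045: 1
  rng_seed: 0
  setting_designs:
    PHH:
      dose_levels:
      - low
      - middle
      - high
      n_replicates: 2
      times_hr:
      - 2.0
      - 8.0
      - 24.0
    PRH:
      dose_levels:
      - low
      - middle
      - high
      n_replicates: 2
      times_hr:
      - 2.0
      - 8.0
      - 24.0
    RLV:
      dose_levels:
      - low
      - middle
      - high
      n_replicates: 3
      times_hr:
      - 3.0
      - 6.0
      - 9.0
      - 24.0
  settings:
  - RLV
  - PRH
  - PHH
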