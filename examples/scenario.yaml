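# Synthetic survey scenario for `occutrend simulate` / `occutrend all`.
# Defaults mirror the study design: 190 of 4,500 frame cells, 3 seasons,
# 4 single-night visits, 20% legacy sites.
seed: 1
n_sites: 190
T: 3
J: 4
preset: declining        # stable | declining | hoary-2010 | little-brown-2010
legacy_fraction: 0.2
n_cells: 4500
missingness: 0.0
first_year: 2016
corr_forest_precip: 0.7
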