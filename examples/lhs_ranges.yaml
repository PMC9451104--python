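# Example Latin-hypercube ranges for the 15 explorable model parameters
# (all parameters except the two initial populations, which have virtually
# no effect on end-states). These bounds are a fixture choice of this
# package: they bracket the scales used by the shipped presets — per-capita
# cross-utilities of order 1, baseline utilities of order 10-100, growth
# rates well inside the stable regime of the discrete logistic map.
number_types_humans: [2, 30]
number_types_plants: [2, 30]
undirected_variation_humans: [0.0, 0.25]
undirected_variation_plants: [0.0, 0.25]
intrinsic_growth_rate_humans: [0.01, 0.25]
intrinsic_growth_rate_plants: [0.01, 0.25]
utility_per_capita_type_n_plants_to_humans: [0.0, 2.0]
utility_per_capita_type_1_plants_to_humans: [0.0, 2.0]
utility_per_capita_type_n_humans_to_plants: [0.0, 2.0]
utility_per_capita_type_1_humans_to_plants: [0.0, 2.0]
utility_other_to_type_n_plants: [0.0, 200.0]
utility_other_to_type_1_plants: [0.0, 200.0]
utility_other_to_type_n_humans: [0.0, 200.0]
utility_other_to_type_1_humans: [0.0, 200.0]
max_area: [100.0, 2000.0]
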