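# GeneratorConfig overrides for `delivcare generate` / `delivcare run --generate`.
# Omitted keys keep the study defaults (71 countries x 600 women; see
# docs/methods.md for the full table).
n_countries: 6
women_per_country: 400
n_strata_per_country: 4
n_psu_per_stratum: 2
p_facility: [0.3, 0.45, 0.6, 0.75, 0.9, 0.97]
wealth_gradient: 0.5
missingness_rate: 0.03
mmr_intercept: 900.0
mmr_slope: -8.0
mmr_noise_sd: 120.0
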