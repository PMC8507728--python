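baseline_sd: 1.25
depth_bounds:
- 3000
- 240000
depth_meanlog: 9.903487552536127
depth_sdlog: 0.6
effect: 2.0
grade_slope: 1.0
interaction_cell:
- '3'
- right_transverse
interaction_effect: 2.0
n_genera: 30
n_grade_slope_genera: 0
n_interaction_genera: 0
n_mucosa: 6
n_patients: 12
n_stool: 6
n_subtypes: 3
n_tumour: 0
n_tumour_specific: 6
noise_sd: 1.0
patient_sd: 0.5
seed: 20210925
signature_size: 2
subtype_effect: 2.0
subtype_weights:
- 0.26
- 0.31
- 0.43
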