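# Middle childhood (9 y). GFR and fu_p must be supplied explicitly; MPPGL
# is set equal to the adult value pending population-specific data.
label: middle childhood
age_years: 9
weight_kg: 34.45
liver_weight_g: 906.24
MPPGL_mg_per_g: 38
GFR: null
GFR_unit: mL/min
fu_p: null
enzyme_abundance: {}
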