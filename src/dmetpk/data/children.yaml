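# Children (7 y). GFR and fu_p must be supplied explicitly; MPPGL is set
# equal to the adult value pending population-specific data.
label: children
age_years: 7
weight_kg: 26.54
liver_weight_g: 726.23
MPPGL_mg_per_g: 38
GFR: null
GFR_unit: mL/min
fu_p: null
enzyme_abundance: {}
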