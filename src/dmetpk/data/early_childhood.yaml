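# Early childhood (4 y). GFR and fu_p are not published for this group and
# must be supplied explicitly before renal-clearance scaling; MPPGL is set
# equal to the adult value pending population-specific data.
label: early childhood
age_years: 4
weight_kg: 17.34
liver_weight_g: 592.12
MPPGL_mg_per_g: 38
GFR: null
GFR_unit: mL/min
fu_p: null
enzyme_abundance: {}
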