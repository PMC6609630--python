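# Hepatic impairment, Child-Pugh C, hepatitis C virus cirrhosis (30 y).
# UGT1A4 abundance in HCV cirrhotic liver is reported 4-fold lower than
# healthy liver; the pooled adult mean 46.77 pmol/mg gives 11.6925.
# GFR and fu_p must be supplied explicitly.
label: HI Child-Pugh C (HCV cirrhosis)
age_years: 30
weight_kg: 70
liver_weight_g: 867.97
MPPGL_mg_per_g: 38
GFR: null
GFR_unit: mL/min
fu_p: null
enzyme_abundance:
  UGT1A4_pooled:
    mean: 11.6925
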