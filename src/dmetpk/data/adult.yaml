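# Healthy adult reference physiology (30 y, 70 kg).
#
# Q_HB is a calibration constant, not a measured value: it is the hepatic
# blood flow under which the well-stirred back-calculation maps the
# lamotrigine hepatic clearance (1.8 L/h, fu_p 0.45, B:P 1) onto an unbound
# intrinsic hepatic clearance of exactly 4.09 L/h.
#
# UGT1A3/UGT1A4 under enzyme_abundance are the simulator-default microsomal
# abundances used in the IVIVE chain; UGT1A4_pooled carries the published
# pooled weighted mean and method-II 95% CI bounds used for variability
# scale factors.
label: healthy adult
age_years: 30
weight_kg: 70
Q_HB_L_per_h: 81.8
MPPGL_mg_per_g: 38
liver_weight_g: 1637.7
GFR: 120
GFR_unit: mL/min
fu_p: 0.45
enzyme_abundance:
  UGT1A3:
    mean: 7.6
  UGT1A4:
    mean: 7.9
  UGT1A4_pooled:
    mean: 46.77
    ci_low: 30.88
    ci_high: 70.82
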