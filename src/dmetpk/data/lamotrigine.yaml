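# Lamotrigine disposition parameters (clinical IV clearance split into
# renal and hepatic shares; glucuronidation accounts for 0.86 of clearance,
# split 10%/90% across UGT1A3/UGT1A4; a minor CYP pathway carries 0.04).
name: lamotrigine
CL_IV_L_per_h: 2.0
f_CL_renal: 0.10
fu_p: 0.45
BP: 1.0
fu_mic: 1.0
f_m:
  UGT1A3: 0.086
  UGT1A4: 0.774
  CYP: 0.040
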