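# Enzyme kinetics for the lamotrigine glucuronidation pathway:
# in vitro Km and simulator-default liver microsomal abundances.
enzyme,Km_uM,abundance_pmol_per_mg,ISEF
UGT1A3,70,7.6,1.0
UGT1A4,550,7.9,1.0
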