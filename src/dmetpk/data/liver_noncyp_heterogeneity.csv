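# Published heterogeneity summaries for hepatic non-CYP enzymes in liver
# microsomes (fixed-effect and random-effects models). Q and df are the
# reconstruction inputs; H2, I2_pct, P_value and het_class are the printed
# reference values they should reproduce.
enzyme,model,Q,df,H2,I2_pct,P_value,het_class
UGT1A1,FE,8.14,8,1.02,1.74,0.42,low
UGT1A1,RE,7.92,8,0.99,0.00,0.44,none
UGT1A3,FE,2.56,5,0.51,0.00,0.77,none
UGT1A3,RE,2.56,5,0.51,0.00,0.77,none
UGT1A4,FE,24.66,5,4.93,79.73,0.00016,high
UGT1A4,RE,3.23,5,0.65,0.00,0.66,none
UGT1A6,FE,8.53,6,1.42,29.67,0.20,low
UGT1A6,RE,7.50,6,1.25,19.97,0.28,low
UGT1A9,FE,3.99,6,0.67,0.00,0.68,none
UGT1A9,RE,3.99,6,0.67,0.00,0.68,none
UGT2B4,FE,2.71,3,0.90,0.00,0.44,none
UGT2B4,RE,2.71,3,0.90,0.00,0.44,none
UGT2B7,FE,31.24,6,5.21,80.79,0.000023,high
UGT2B7,RE,6.87,6,1.14,12.63,0.33,low
UGT2B10,FE,3.89,2,1.95,48.65,0.14,medium
UGT2B10,RE,3.49,2,1.75,42.77,0.17,medium
UGT2B15,FE,6.61,5,1.32,24.33,0.25,low
UGT2B15,RE,5.41,5,1.08,7.52,0.37,low
UGT2B17,FE,1.27,3,0.42,0.00,0.74,none
UGT2B17,RE,1.27,3,0.42,0.00,0.74,none
CES1,FE,2.41,1,2.41,58.45,0.12,medium
CES1,RE,1.00,1,1.00,0.00,0.32,none
FMO3,FE,1.27,2,0.63,0.00,0.53,none
FMO3,RE,1.27,2,0.63,0.00,0.53,none
FMO5,FE,0.18,1,0.18,0.00,0.67,none
FMO5,RE,0.18,1,0.18,0.00,0.67,none
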