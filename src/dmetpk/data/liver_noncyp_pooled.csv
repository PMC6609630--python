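# Published pooled summaries for hepatic non-CYP enzymes in liver
# microsomes: sample-size-weighted mean abundance (pmol/mg microsomal
# protein), pooled %CV by three estimators, geometric 95% CI bounds
# (z = 1.96) and the number of studies k. WM, cv_pct and k are the
# reconstruction inputs; ci_low and ci_high are the printed reference
# bounds they should reproduce.
# consistent=0 marks the one printed row whose CI bounds do not
# satisfy the geometric-CI relation given its own WM/%CV/k.
enzyme,method,WM,cv_pct,ci_low,ci_high,k,consistent
UGT1A1,I,35.97,72.36,23.54,54.97,9,1
UGT1A1,II,35.97,102.97,20.64,62.69,9,1
UGT1A1,III,35.97,62.78,24.68,52.42,9,1
UGT1A3,I,25.01,154.67,10.33,60.56,6,1
UGT1A3,II,25.01,238.29,8.30,75.33,6,1
UGT1A3,III,25.01,78.45,14.37,43.53,6,1
UGT1A4,I,46.77,36.96,35.12,62.27,6,1
UGT1A4,II,46.77,55.55,30.88,70.82,6,1
UGT1A4,III,46.77,40.92,34.14,64.08,6,1
UGT1A6,I,29.71,132.67,14.08,62.67,7,1
UGT1A6,II,29.71,169.39,12.55,70.32,7,1
UGT1A6,III,29.71,50.58,20.86,42.31,7,1
UGT1A9,I,27.38,41.72,20.35,36.84,7,1
UGT1A9,II,27.38,66.76,17.46,42.93,7,1
UGT1A9,III,27.38,45.27,19.89,37.70,7,1
UGT2B4,I,49.43,44.90,32.48,75.22,4,1
UGT2B4,II,49.43,65.21,27.58,88.58,4,1
UGT2B4,III,49.43,39.24,34.11,71.62,4,1
UGT2B7,I,75.21,55.48,51.24,110.40,7,1
UGT2B7,II,75.21,69.69,47.19,119.87,7,1
UGT2B7,III,75.21,37.38,57.54,98.32,7,1
UGT2B10,I,14.72,142.73,4.47,48.51,3,1
UGT2B10,II,14.72,166.74,3.99,54.28,3,1
UGT2B10,III,14.72,74.75,6.93,31.28,3,1
UGT2B15,I,41.50,52.90,27.89,61.75,6,1
UGT2B15,II,41.50,71.75,24.78,69.50,6,1
UGT2B15,III,41.50,41.75,30.11,57.19,6,1
UGT2B17,I,5.84,198.79,1.69,20.19,4,1
UGT2B17,II,5.84,324.38,1.26,27.05,4,1
UGT2B17,III,5.84,138.85,2.12,16.14,4,1
CES1,I,1252.93,45.92,683.36,2297.24,2,1
CES1,II,1252.93,69.68,523.92,2996.31,2,1
CES1,III,1252.93,43.74,355.23,4419.19,2,0
FMO3,I,29.33,21.58,23.03,37.34,3,1
FMO3,II,29.33,58.81,15.83,54.34,3,1
FMO3,III,29.33,53.71,16.59,51.84,3,1
FMO5,I,24.63,15.10,20.00,30.32,2,1
FMO5,II,24.63,54.98,12.08,50.21,2,1
FMO5,III,24.63,55.08,12.07,50.27,2,1
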