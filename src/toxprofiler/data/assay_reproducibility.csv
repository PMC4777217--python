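assay,pct_active_match,pct_inactive_match,pct_inconclusive,pct_mismatch,ac50_fold_change,published_score
ATAD5,5.34,91.78,2.84,0.05,1.30,99.51
DT40 Rad54/Ku70,23.92,59.47,16.50,0.10,1.32,90.61
DT40 Rev3,22.38,58.07,19.29,0.26,1.40,83.02
DT40 WT,21.07,58.89,18.65,1.39,1.49,79.58
P53-bla,11.10,84.86,4.04,0.00,1.29,103.02
ARE-bla,15.29,68.34,15.65,0.70,1.76,81.85
HSE-bla,7.57,86.38,6.05,0.00,1.45,95.46
Aromatase,15.94,73.08,10.66,0.30,1.44,93.66
Mitochondria toxicity,17.57,67.52,14.33,0.55,1.53,87.20
AhR-luc,8.86,78.78,12.24,0.10,1.82,84.05
AR-bla agonist,5.36,86.88,7.44,0.30,1.77,89.55
AR-bla antagonist,15.46,75.07,9.38,0.09,1.35,96.44
AR-MDA-luc agonist,4.14,93.65,2.20,0.00,1.36,99.74
AR-MDA-luc antagonist,13.22,76.44,10.07,0.27,1.48,92.28
ER-BG1-luc agonist,16.43,71.22,12.05,0.28,1.52,91.46
ER-BG1-luc antagonist,12.03,79.72,7.96,0.29,1.48,95.25
ER-bla agonist,7.01,87.11,5.87,0.01,1.36,95.25
ER-bla antagonist,9.84,77.86,11.95,0.34,1.49,84.90
FXR-bla agonist,2.46,93.87,3.65,0.02,1.53,95.09
FXR-bla antagonist,7.50,83.04,9.35,0.11,1.73,88.48
GR-bla agonist,6.67,87.49,5.75,0.10,1.37,94.89
GR-bla antagonist,9.73,75.11,13.13,2.01,1.81,77.40
PPAR-delta-bla agonist,3.46,90.79,5.71,0.04,1.71,91.91
PPAR-delta-bla antagonist,5.67,86.73,7.49,0.10,1.73,90.37
PPAR-gamma-bla agonist,8.79,83.87,7.02,0.31,1.61,93.81
PPAR-gamma-bla antagonist,8.61,79.88,11.05,0.44,1.90,85.15
TR-beta-luc agonist,2.13,90.72,7.15,0.00,1.38,87.84
TR-beta-luc antagonist,17.15,68.35,14.18,0.32,1.39,87.82
VDR-bla agonist,2.25,92.53,5.19,0.03,1.62,91.79
VDR-bla antagonist,5.41,86.41,8.11,0.08,1.53,88.97
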