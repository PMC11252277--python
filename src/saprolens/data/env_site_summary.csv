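variable,unit,mean_I,sd_I,mean_II,sd_II,mean_III,sd_III,mean_IV,sd_IV,mean_V,sd_V,mean_VI,sd_VI
Temp,degC,26.97,6.59,27.75,6.53,26.81,6.82,24.66,5.95,25.02,6.01,24.69,5.53
pH,,8.26,0.25,8.27,0.17,8.35,0.22,8.23,0.22,8.16,0.18,8.1,0.19
Turb,NTU,3.28,0.88,4.26,1.24,4.65,1.68,4.68,2.46,5.24,1.83,5.96,1.92
TDS,mg/L,274.08,37.78,278.67,40.93,277.9,42.08,279.08,46.67,278.42,45.64,280.25,47.88
EC,uS/cm,414.42,61.79,428.67,63.14,427.5,65.01,428.42,71.88,428.25,70.15,429.08,69.49
Cl,mg/L,35.5,9.27,36.67,9.12,36.0,9.15,36.75,10.06,36.33,11.53,37.25,10.58
THard,mg/L,168.83,5.22,168.17,5.94,168.17,4.78,170.17,4.93,169.5,4.91,169.17,4.93
Ca,mg/L,40.07,0.8,39.67,0.87,39.8,1.14,40.13,0.82,40.07,0.8,40.2,0.77
Mg,mg/L,16.56,1.27,16.56,1.4,16.52,1.41,16.76,1.11,16.56,1.13,16.48,1.3
Alk,mg/L,136.83,17.71,140.0,18.51,139.5,19.22,139.83,19.27,139.83,18.63,139.0,18.83
Na,mg/L,39.58,5.95,39.08,5.95,38.83,5.78,39.33,5.99,39.0,5.74,38.83,5.41
K,mg/L,5.7,0.28,5.7,0.27,5.72,0.31,5.75,0.28,5.72,0.31,5.74,0.33
DO,mg/L,7.93,1.38,7.85,1.7,8.3,1.49,8.28,1.71,8.12,1.66,7.83,1.7
COD,mg/L,44.96,13.26,36.57,19.34,58.17,46.74,41.13,31.69,52.02,46.83,59.79,48.07
BOD,mg/L,4.9,2.58,6.77,2.93,8.23,3.91,5.08,2.2,5.68,3.03,8.46,4.39
NH3,ug/L,302.67,133.26,291.0,125.9,292.0,125.36,314.17,140.1,319.0,135.17,334.08,149.16
NO2,ug/L,20.0,2.26,20.83,3.46,19.5,2.97,22.42,2.35,22.33,3.42,21.92,2.91
PO4,ug/L,120.0,8.53,139.17,13.11,133.33,16.14,145.0,10.0,165.0,15.67,169.17,9.0
SiO3,ug/L,1144.2,599.14,1153.3,595.3,1147.5,592.32,1165.0,600.7,1209.2,629.62,1229.2,637.56
TOC,mg/L,5.49,0.85,5.62,0.98,5.96,1.35,5.72,1.1,5.55,0.87,5.37,1.05
SO4,mg/L,29.75,2.05,30.42,2.91,28.83,1.4,30.0,1.48,30.08,1.62,31.75,1.82
F,ug/L,377.42,13.44,374.58,11.8,373.6,13.6,373.17,13.85,372.92,15.7,371.92,16.05
Al,ug/L,43.33,18.75,47.5,10.55,49.17,13.11,90.81,14.97,50.0,23.35,65.0,21.95
Fe,ug/L,34.67,22.03,45.75,28.42,46.08,45.02,32.5,33.34,55.75,41.44,75.88,56.32
Mn,ug/L,25.5,16.67,29.67,21.47,30.0,29.6,23.58,13.98,26.83,14.12,34.17,22.11
Cd,ug/L,0.04,0.04,0.05,0.04,0.04,0.05,0.12,0.04,0.12,0.06,0.05,0.05
Cu,ug/L,0.42,1.44,1.0,3.16,2.67,4.08,0.17,0.58,0.5,1.45,2.08,4.14
Ni,ug/L,1.69,0.88,1.08,1.45,0.52,0.21,0.93,1.4,0.53,0.29,0.57,0.26
Pb,ug/L,0.4,0.28,0.31,0.21,0.34,0.24,1.22,0.22,0.31,0.21,0.63,0.25
Zn,ug/L,3.31,4.89,2.48,4.05,1.07,1.66,4.93,6.51,1.71,3.9,1.45,3.34
Chl_a,ug/L,7.11,4.8,6.21,2.98,7.64,3.25,7.49,3.09,5.91,2.28,5.29,2.82
HPC,CFU/mL,506.67,379.77,645.0,505.6,615.83,358.29,802.5,627.0,590.83,465.28,651.67,453.41
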