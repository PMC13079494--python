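name,rt,rt_sd,rrt,rrt_sd,ion_ratio_low,ion_ratio_low_sd,ion_ratio_high,ion_ratio_high_sd,linearity,idl,iql,intraday_accuracy,intraday_precision,interday_accuracy,interday_precision,status,label_rule_determined,one_transition_cap
PFBS,7.80,0.01,1.00,0.00,0.52,0.10,0.52,0.01,0.9997,0.0033,0.01,98.7,7.0,99.1,13.3,quantitative,1,0
PFHxS,9.05,0.02,1.16,0.00,1.59,0.26,1.63,0.03,0.9995,0.033,0.1,97.1,6.5,97.3,5.8,quantitative,1,0
PFHpS,9.70,0.01,1.00,0.00,66.36,39.67,44.07,10.62,0.9981,16.5,50,129.9,6.8,123.1,8.4,semi_quantitative,0,0
PFOS,10.30,0.03,1.06,0.00,6.22,4.39,3.80,0.37,0.9982,0.165,0.5,140.7,21.1,141.0,10.1,semi_quantitative,0,0
PFNS,10.88,0.01,1.13,0.00,9.48,7.19,5.94,1.45,0.9901,8.25,25,113.0,13.6,102.9,20.9,quantitative,1,0
PFOSA,11.69,0.09,1.50,0.01,,,23.30,10.70,0.9396,33,100,83.1,26.5,77.9,28.8,semi_quantitative,0,0
n-MeFOSA,12.62,0.03,1.31,0.00,,,1.62,0.72,0.9228,33,100,91.4,24.6,84.7,30.4,semi_quantitative,0,0
n-EtFOSA,13.02,0.14,1.35,0.01,2.62,2.23,1.43,0.20,0.9917,16.5,50,62.7,10.9,52.4,20.0,quantitative,1,0
n-MeFOSAA,11.22,0.03,1.10,0.00,3.39,4.70,2.03,0.10,0.9907,0.33,1,90.5,14.5,85.4,16.3,quantitative,1,0
n-EtFOSAA,11.50,0.03,1.39,0.01,3.90,2.06,2.91,0.17,0.9935,3.3,10,84.3,19.9,69.4,25.2,quantitative,1,0
PFBA,6.99,0.02,0.99,0.03,,,,,0.9993,0.0033,0.01,84.6,21.6,87.9,20.2,quantitative,1,0
PFPeA,7.71,0.02,0.75,0.00,737.55,1153.64,425.40,80.43,0.9984,3.3,10,109.6,4.1,114.4,8.7,quantitative,1,0
PFHxA,8.39,0.03,0.82,0.00,14.03,3.46,12.62,0.41,0.998,0.165,0.5,90.2,25.7,102.1,30.3,quantitative,1,0
PFHpA,9.05,0.03,0.88,0.00,5.78,8.26,4.04,0.16,0.9985,0.0165,0.05,104.2,23.1,118.9,25.4,quantitative,1,0
PFOA,9.70,0.03,1.00,0.00,3.51,2.08,3.00,0.10,0.9997,0.0165,0.05,87.3,5.4,88.8,5.1,quantitative,1,0
PFNA,10.32,0.02,1.06,0.00,4.73,0.97,4.21,0.12,0.9910,0.33,1,119.0,27.9,118.9,28.8,quantitative,1,0
PFDA,10.90,0.02,1.12,0.00,7.26,3.98,5.38,0.24,0.9989,0.165,0.5,102.7,27.6,100.0,22.1,quantitative,1,0
PFUnDA,11.43,0.02,1.18,0.00,9.46,5.30,7.23,0.53,0.9954,3.3,10,116.3,23.3,114.6,24.9,quantitative,1,0
PFDoDA,11.96,0.06,1.23,0.00,6.38,2.89,5.30,0.36,0.9948,1.65,5,94.8,19.7,93.4,28.7,quantitative,1,0
PFTrDA,12.37,0.01,1.28,0.00,1.65,0.36,1.61,0.05,0.9861,0.165,0.5,41.3,13.7,35.0,17.0,semi_quantitative,1,0
PFTeDA,12.79,0.02,1.55,0.01,5.08,1.17,5.29,0.08,0.9899,0.0033,0.01,39.7,11.7,33.6,10.4,semi_quantitative,1,0
6:2 FTS,9.69,0.03,1.00,0.00,14.97,18.69,9.30,0.35,0.9999,0.165,0.5,102.0,4.4,101.1,6.7,quantitative,1,0
8:2 FTS,10.94,0.06,1.13,0.00,2.02,1.03,1.75,0.07,0.9975,0.165,0.5,114.2,17.4,111.7,12.2,quantitative,1,0
5:3 FTC,9.55,0.11,1.22,0.02,1.07,0.18,1.09,0.05,0.9959,0.033,0.1,74.4,22.1,76.4,23.8,quantitative,1,0
6:2 diPAP,12.56,0.17,1.61,0.03,1.57,0.34,1.56,0.09,0.9951,3.3,10,109.2,9.0,101.7,14.9,quantitative,1,0
8:2 diPAP,13.81,0.01,1.77,0.01,1.99,0.11,1.98,0.047,0.9924,0.0033,0.01,149.1,11.5,147.6,25.7,semi_quantitative,0,0
PFHxPA,9.05,0.02,0.93,0.00,4.36,1.21,4.13,0.10,0.9973,0.033,0.1,95.3,20.9,92.9,23.4,quantitative,1,0
PFOPA,9.69,0.03,1.00,0.00,,,,,0.9988,0.165,0.5,97.5,7.0,104.3,24.2,semi_quantitative,1,1
PFDPA,10.93,0.03,1.13,0.00,,,,,0.9961,0.165,0.5,91.8,20.3,89.1,24.8,semi_quantitative,1,1
6:6 PFPiA,11.83,0.02,1.22,0.00,,,6.47,0.32,0.9917,0.165,0.5,101.3,29.5,88.3,22.7,quantitative,1,0
8:8 PFPiA,13.13,0.01,1.35,0.00,,,,,0.9940,0.0165,0.05,51.7,28.8,46.9,28.2,semi_quantitative,1,1
8:2 monoPAP,10.80,0.03,1.12,0.00,14.07,22.74,7.61,0.54,0.9963,0.033,0.1,39.7,24.0,48.3,7.5,semi_quantitative,1,0
Gen X,8.57,0.01,1.10,0.00,1.88,0.56,1.84,0.06,0.9987,0.033,0.1,88.8,23.2,92.2,18.3,quantitative,1,0
ADONA,9.06,0.02,1.16,0.00,2.58,0.90,2.34,0.15,0.9995,0.033,0.1,92.2,10.8,90.4,11.6,quantitative,1,0
9ClPF3ONS,10.55,0.02,1.97,0.01,69.59,19.81,61.67,6.05,0.9962,8.25,25,55.6,9.2,56.6,9.6,quantitative,1,0
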