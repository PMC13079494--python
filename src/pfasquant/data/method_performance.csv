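name,status,rt,rt_sd,rrt,rrt_sd,ion_ratio,ion_ratio_sd,recovery,recovery_sd,mdl,mql,accuracy,precision
PFBS,quantitative,7.71,0.02,1.00,0.00,0.51,0.17,118.2,18.5,0.03,0.08,80.5,4.7
PFHxS,quantitative,8.99,0.02,1.17,0.00,1.70,0.22,110.4,18.3,0.3,0.9,91.0,8.9
PFHpS,semi_quantitative,9.64,0.02,1.00,0.00,40.47,7.68,103.2,13.2,159.9,484.6,86.2,11.5
PFOS,semi_quantitative,10.23,0.08,1.06,0.01,4.71,1.25,170.8,31.8,1.0,2.9,92.7,20.8
PFNS,quantitative,10.31,0.00,1.10,0.00,6.76,2.61,80.9,18.7,102.0,308.9,98.9,23.2
PFOSA,semi_quantitative,11.73,0.08,1.52,0.01,41.71,16.77,70.6,27.0,467.2,1415.8,111.9,42.6
n-MeFOSA,semi_quantitative,12.68,0.13,1.32,0.01,2.26,1.71,43.6,0.6,756.9,2293.6,99.8,1.7
n-EtFOSA,quantitative,12.97,0.09,1.35,0.01,1.33,1.14,33.2,1.4,496.7,1505.1,94.0,2.5
n-MeFOSAA,quantitative,10.99,0.03,1.08,0.02,1.59,0.99,44.4,19.1,7.4,22.5,90.4,36.8
n-EtFOSAA,quantitative,11.26,0.02,1.41,0.01,5.14,4.72,31.1,13.8,106.2,321.9,136.3,32.0
PFBA,quantitative,6.92,0.04,0.98,0.04,,,122.7,31.5,0.03,0.08,90.4,15.4
PFPeA,quantitative,7.62,0.02,0.75,0.01,595.74,376.73,104.0,19.0,31.8,96.2,146.6,24.4
PFHxA,quantitative,8.32,0.01,0.82,0.01,14.43,2.38,125.0,28.3,1.3,4.0,123.8,25.6
PFHpA,quantitative,8.97,0.02,0.88,0.01,4.32,0.60,128.3,27.5,0.1,0.4,95.1,20.4
PFOA,quantitative,9.64,0.02,1.00,0.00,3.27,0.42,113.0,21.2,0.2,0.4,87.9,7.4
PFNA,quantitative,10.25,0.02,1.06,0.00,4.49,0.67,149.5,25.6,2.2,6.7,85.4,20.4
PFDA,quantitative,10.74,0.02,1.11,0.00,9.22,6.72,103.2,31.3,1.6,4.9,108.4,18.2
PFUnDA,quantitative,11.20,0.02,1.16,0.00,12.50,24.11,50.1,24.5,65.9,199.8,68.9,15.4
PFDoDA,quantitative,11.75,0.02,1.22,0.00,8.76,4.21,44.0,11.4,37.5,113.7,85.6,6.2
PFTrDA,semi_quantitative,12.30,0.02,1.28,0.00,1.46,0.56,11.5,5.2,14.3,43.3,68.9,29.6
PFTeDA,semi_quantitative,12.77,0.02,1.60,0.01,5.80,1.02,7.6,2.9,0.4,1.3,119.7,28.3
6:2 FTS,quantitative,9.64,0.02,1.00,0.00,10.40,2.43,110.4,15.8,1.5,4.5,75.5,8.8
8:2 FTS,quantitative,10.33,0.01,1.10,0.00,1.85,0.50,296.3,61.9,0.6,1.7,59.0,9.1
5:3 FTC,quantitative,9.42,0.02,1.22,0.00,1.06,0.20,107.6,20.4,0.3,0.9,88.4,27.9
6:2 diPAP,quantitative,12.50,0.03,1.62,0.00,1.71,0.33,20.8,5.7,158.8,481.2,131.0,27.9
8:2 diPAP,semi_quantitative,14.94,0.02,1.95,0.09,2,0.16,16.8,6.1,0.2,0.6,129.0,18.1
PFHxPA,quantitative,8.98,0.02,0.93,0.00,5.22,1.70,135.3,15.5,0.2,0.7,91.7,26.2
PFOPA,semi_quantitative,9.52,0.02,0.99,0.00,,,107.6,30.5,1.5,4.7,94.3,5.6
PFDPA,semi_quantitative,10.34,0.02,1.10,0.00,,,239.1,73.5,0.7,2.1,86.1,14.0
6:6 PFPiA,quantitative,11.67,0.02,1.21,0.00,11.33,5.90,45.5,16.4,3.6,11.0,63.3,5.8
8:8 PFPiA,semi_quantitative,13.13,0.02,1.36,0.00,,,6.3,1.7,2.6,8.0,114.3,25.5
8:2 monoPAP,semi_quantitative,10.71,0.12,1.11,0.01,,,,,,,,
Gen X,quantitative,8.49,0.01,1.10,0.00,1.84,0.32,103.3,18.8,0.3,1.0,71.4,16.7
ADONA,quantitative,8.99,0.01,1.17,0.00,2.26,0.83,75.7,12.2,0.4,1.3,69.7,13.8
9ClPF3ONS,quantitative,10.46,0.01,1.96,0.02,61.26,5.60,114.0,22.5,72.4,219.3,93.7,13.8
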