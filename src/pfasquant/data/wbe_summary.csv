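analyte,detection_frequency,cumulative_conc,cumulative_conc_sd,dl,dl_sd,pndl,pndl_sd,conc_consistent
PFBS,2,43.8,13.5,10039,3092,12,3,1
PFBA,1,0,,0,,0,,1
PFHpA,1,0,,0,,0,,1
PFOA,3,8.5,0.6,1935,147,4,0.2,1
PFNA,1,20.1,0.00,13825,0,17,0,0
PFDA,1,22.3,0.00,5099,0,6,0,1
6:2 FTS,1,0,,0,,0,,1
8:2 diPAP,3,198.1,109.1,45369,24984,55,30,1
PFOPA,3,85.4,23.1,19563,5296,24,6,1
PFDPA,3,92.9,28.4,21280,6500,26,8,1
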