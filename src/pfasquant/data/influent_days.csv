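analyte,day,censor,value
PFBS,1,detected,31.5
PFBS,2,below_LOD,
PFBS,3,detected,12.4
PFHxS,1,below_LOD,
PFHxS,2,below_LOD,
PFHxS,3,below_LOD,
PFHpS,1,below_LOD,
PFHpS,2,below_LOD,
PFHpS,3,below_LOD,
PFOS,1,below_LOD,
PFOS,2,below_LOD,
PFOS,3,below_LOD,
PFNS,1,below_LOD,
PFNS,2,below_LOD,
PFNS,3,below_LOD,
PFOSA,1,below_LOD,
PFOSA,2,below_LOD,
PFOSA,3,below_LOD,
n-MeFOSA,1,below_LOD,
n-MeFOSA,2,below_LOD,
n-MeFOSA,3,below_LOD,
n-EtFOSA,1,below_LOD,
n-EtFOSA,2,below_LOD,
n-EtFOSA,3,below_LOD,
n-MeFOSAA,1,below_LOD,
n-MeFOSAA,2,below_LOD,
n-MeFOSAA,3,below_LOD,
n-EtFOSAA,1,below_LOD,
n-EtFOSAA,2,below_LOD,
n-EtFOSAA,3,below_LOD,
PFBA,1,below_LOQ,
PFBA,2,below_LOD,
PFBA,3,below_LOD,
PFPeA,1,below_LOD,
PFPeA,2,below_LOD,
PFPeA,3,below_LOD,
PFHxA,1,below_LOD,
PFHxA,2,below_LOD,
PFHxA,3,below_LOD,
PFHpA,1,below_LOQ,
PFHpA,2,below_LOD,
PFHpA,3,below_LOD,
PFOA,1,detected,3.6
PFOA,2,detected,2.4
PFOA,3,detected,2.5
PFNA,1,below_LOD,
PFNA,2,below_LOD,
PFNA,3,detected,60.4
PFDA,1,detected,22.3
PFDA,2,below_LOD,
PFDA,3,below_LOD,
PFUnDA,1,below_LOD,
PFUnDA,2,below_LOD,
PFUnDA,3,below_LOD,
PFDoDA,1,below_LOD,
PFDoDA,2,below_LOD,
PFDoDA,3,below_LOD,
PFTrDA,1,below_LOD,
PFTrDA,2,below_LOD,
PFTrDA,3,below_LOD,
PFTeDA,1,below_LOD,
PFTeDA,2,below_LOD,
PFTeDA,3,below_LOD,
6:2 FTS,1,below_LOD,
6:2 FTS,2,below_LOD,
6:2 FTS,3,below_LOQ,
8:2 FTS,1,below_LOD,
8:2 FTS,2,below_LOD,
8:2 FTS,3,below_LOD,
5:3 FTC,1,below_LOD,
5:3 FTC,2,below_LOD,
5:3 FTC,3,below_LOD,
6:2 diPAP,1,below_LOD,
6:2 diPAP,2,below_LOD,
6:2 diPAP,3,below_LOD,
8:2 diPAP,1,detected,176.2
8:2 diPAP,2,detected,21.9
8:2 diPAP,3,below_LOQ,
PFHxPA,1,below_LOD,
PFHxPA,2,below_LOD,
PFHxPA,3,below_LOD,
PFOPA,1,detected,54.8
PFOPA,2,detected,19.3
PFOPA,3,detected,11.4
PFDPA,1,detected,63.4
PFDPA,2,detected,18.6
PFDPA,3,detected,10.9
6:6 PFPiA,1,below_LOD,
6:6 PFPiA,2,below_LOD,
6:6 PFPiA,3,below_LOD,
8:8 PFPiA,1,below_LOD,
8:8 PFPiA,2,below_LOD,
8:8 PFPiA,3,below_LOD,
8:2 monoPAP,1,below_LOD,
8:2 monoPAP,2,below_LOD,
8:2 monoPAP,3,below_LOD,
Gen X,1,below_LOD,
Gen X,2,below_LOD,
Gen X,3,below_LOD,
ADONA,1,below_LOD,
ADONA,2,below_LOD,
ADONA,3,below_LOD,
9ClPF3ONS,1,below_LOD,
9ClPF3ONS,2,below_LOD,
9ClPF3ONS,3,below_LOD,
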