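name,analyte_class,quant_precursor,quant_product,quant_cv,quant_ce,qual_precursor,qual_product,qual_cv,qual_ce,istd,calib_low,calib_high,status
PFBS,PFSA,298.90,98.9,40,27,298.90,79.9,40,28,PFBS 13C4,0.01,1000,quantitative
PFHxS,PFSA,398.95,79.90,55,37,398.95,98.9,55,32,PFBS 13C4,0.1,500,quantitative
PFHpS,PFSA,448.80,168.95,50,31,448.80,229.90,50,22,6:2 FTS 13C2 D4,50,600,semi_quantitative
PFOS,PFSA,498.80,98.9,41,41,498.80,169,41,34,6:2 FTS 13C2 D4,0.5,400,semi_quantitative
PFNS,PFSA,548.90,98.9,50,45,548.90,118.90,50,45,6:2 FTS 13C2 D4,25,600,quantitative
PFOSA,PFSA_precursor,497.80,77.9,44,43,497.80,168.9,44,26,PFBS 13C4,100,800,semi_quantitative
n-MeFOSA,PFSA_precursor,511.90,168.9,45,26,511.90,218.9,45,25,6:2 FTS 13C2 D4,100,1000,semi_quantitative
n-EtFOSA,PFSA_precursor,525.80,169.0,39,28,525.80,218.90,39,24,6:2 FTS 13C2 D4,50,400,quantitative
n-MeFOSAA,PFSA_precursor,569.90,418.95,30,18,569.90,482.90,30,15,Ibuprofen D3,1,500,quantitative
n-EtFOSAA,PFSA_precursor,583.80,218.90,29,26,583.80,418.90,29,19,Ketoprofen D3,10,600,quantitative
PFBA,PFCA,212.90,168.90,17,8,,,,,PFBA 13C4,0.01,1000,quantitative
PFPeA,PFCA,262.90,68.9,15,40,262.90,218.90,15,7,Ibuprofen D3,10,250,quantitative
PFHxA,PFCA,312.9,118.9,12,20,312.9,268.95,12,9,Ibuprofen D3,0.5,200,quantitative
PFHpA,PFCA,362.90,168.90,16,17,362.90,318.90,16,9,Ibuprofen D3,0.05,250,quantitative
PFOA,PFCA,412.90,168.90,20,17,412.90,368.90,20,9,PFOA 13C8,0.05,500,quantitative
PFNA,PFCA,462.8,218.95,17,15,462.80,418.90,17,9,PFOA 13C8,1,600,quantitative
PFDA,PFCA,512.80,218.90,13,15,512.80,468.90,13,11,PFOA 13C8,0.5,400,quantitative
PFUnDA,PFCA,562.90,269.0,15,18,562.90,518.90,15,10,6:2 FTS 13C2 D4,10,400,quantitative
PFDoDA,PFCA,612.80,168.90,19,25,612.80,569.00,19,13,PFOA 13C8,5,100,quantitative
PFTrDA,PFCA,662.80,168.9,18,26,662.80,218.90,18,24,PFOA 13C8,0.5,75,semi_quantitative
PFTeDA,PFCA,712.90,168.9,17,28,712.9,668.9,17,13,Ketoprofen D3,0.01,100,semi_quantitative
6:2 FTS,PFCA_precursor,426.80,386.90,38,26,426.80,407.0,38,21,6:2 FTS 13C2 D4,0.5,600,quantitative
8:2 FTS,PFCA_precursor,526.95,80.95,45,42,526.95,506.95,45,26,6:2 FTS 13C2 D4,0.5,250,quantitative
5:3 FTC,PFCA_precursor,340.9,216.95,23,24,340.9,237.0,23,16,PFBS 13C4,0.1,200,quantitative
6:2 diPAP,PFCA_precursor,788.9,96.9,40,30,788.90,442.90,40,20,Methyl Paraben 13C6,10,1000,quantitative
8:2 diPAP,PFCA_precursor,988.85,96.9,44,35,988.85,542.9,44,23,Methyl Paraben 13C6,0.01,100,semi_quantitative
PFHxPA,phosphonic_phosphinic,398.9,79.9,42,40,398.90,118.90,42,34,PFOA 13C8,0.1,100,quantitative
PFOPA,phosphonic_phosphinic,498.9,78.90,45,31,,,,,6:2 FTS 13C2 D4,0.5,200,semi_quantitative
PFDPA,phosphonic_phosphinic,598.90,78.9,52,40,,,,,6:2 FTS 13C2 D4,0.5,600,semi_quantitative
6:6 PFPiA,phosphonic_phosphinic,700.85,100.9,55,61,700.85,400.9,55,45,PFOA 13C8,0.5,75,quantitative
8:8 PFPiA,phosphonic_phosphinic,900.8,500.8,72,61,,,,,PFOA 13C8,0.05,750,semi_quantitative
8:2 monoPAP,phosphonic_phosphinic,542.90,96.90,30,18,542.90,522.90,30,13,6:2 FTS 13C2 D4,0.1,50,semi_quantitative
Gen X,novel_emerging,284.80,168.90,16,8,284.80,184.90,16,16,PFBS 13C4,0.1,200,quantitative
ADONA,novel_emerging,376.90,84.90,16,26,376.90,250.90,16,10,PFBS 13C4,0.1,250,quantitative
9ClPF3ONS,novel_emerging,530.80,98.90,42,30,530.80,350.90,42,26,Acetaminophen D4,25,1000,quantitative
PFBS 13C4,ISTD,302.9,79.9,40,29,,,,,,,,
PFBA 13C4,ISTD,216.90,171.90,17,8,,,,,,,,
PFOA 13C8,ISTD,420.9,375.9,17,9,,,,,,,,
6:2 FTS 13C2 D4,ISTD,432.90,411.90,40,22,,,,,,,,
Acetaminophen D4,ISTD,154.00,111.00,38,19,,,,,,,,
Methyl Paraben 13C6,ISTD,156.90,97.90,30,20,,,,,,,,
Ketoprofen D3,ISTD,256.00,212.00,15,7,,,,,,,,
Ibuprofen D3,ISTD,208.00,164.00,20,6,,,,,,,,
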