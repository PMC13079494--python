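analyte_name,pnec,organism,exposure_type
PFBS,372000,,unrecorded
PFOA,178,"Insect, Chironomus riparius",chronic
PFNA,1000,"Fish, Pimephales promelas",acute
PFDA,165.3,"Fish, Pimephales promelas",acute
8:2 diPAP,73.3,"Fish, Pimephales promelas",acute
PFOPA,9630,"Fish, Pimephales promelas",acute
PFDPA,290,"Fish, Pimephales promelas",acute
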