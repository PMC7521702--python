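KCNQ1
KCNH2
LMNA
PRKAG2
TPM1
DSG2
PKP2
MYBPC3
MYL3
TNNI3
MYH7
TNNT2
GLA
MYL2
RYR2
SCN5A
DSC2
DSP
ACTC1
TMEM43
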