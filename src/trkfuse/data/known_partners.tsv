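# Partner genes with previously reported NTRK fusions (user-extensible).
ETV6
TPM3
LMNA
TPR
RBPMS
IRF2BP2
PHF20
AMOTL2
COL8A1
PEAR1
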