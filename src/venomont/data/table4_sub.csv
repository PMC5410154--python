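Transcript,ANF-A,ANF-J,LSG-A,LSG-J,BR-A,BR-J,CAL-A,CAL-J,ENP-A,ENP-J
3FTx-1,-,+,+,-,-,-,-,-,+,+
3FTx-2,-,+,+,-,-,-,+,-,-,+
BPP-1,+,+,+,+,+,+,+,+,+,+
CRISP-1,+,+,+,+,+,+,+,+,+,+
CTL-1,+,+,+,+,+,+,+,+,+,+
CTL-2,+,+,+,+,+,+,+,+,+,+
CTL-3,+,+,+,+,+,+,+,+,+,+
CTL-4,+,+,+,+,+,+,+,+,+,+
CTL-5,+,+,+,+,+,+,+,+,+,+
CTL-6,+,+,+,+,+,+,+,+,+,+
CTL-7,+,+,+,+,+,+,+,+,+,+
CTL-8,+,+,+,+,+,+,+,+,+,+
CTL-9,+,+,+,+,+,+,+,+,+,+
CTL-10,+,+,+,+,+,+,+,+,+,+
CTL-11,+,+,+,+,+,+,+,+,-,+
CTL-12,-,-,+,-,-,-,-,-,-,-
CTL-13,+,+,+,+,-,+,-,+,-,+
HYAL-1,+,+,+,+,+,+,+,+,+,+
KUN-1,+,+,+,+,+,+,+,+,+,+
KUN-2,+,+,+,+,+,+,+,+,+,+
LAAO-1,+,+,+,+,+,+,+,+,+,+
MYO-1,+,+,+,+,+,+,+,+,+,+
MYO-2,+,+,+,+,+,+,+,+,+,+
NGF-1,+,+,+,+,+,+,+,-,+,+
NUC-1,+,+,+,+,+,+,+,+,+,+
PDE-1,+,+,+,+,+,+,+,+,+,+
PLA2-1,+,+,+,+,+,+,+,+,+,+
PLA2-2,+,+,+,+,+,+,+,-,+,+
PLB-1,+,+,+,+,+,+,+,+,+,+
SVMPII-1,+,-,+,-,+,-,+,-,+,+
SVMPII-2,+,+,+,+,+,+,+,+,+,+
SVMPII-3,+,-,+,+,+,+,+,-,+,+
SVMPII-4,+,+,+,+,+,+,+,+,+,+
SVMPII-5,+,-,+,-,+,+,+,-,+,+
SVMPIII-1,+,-,+,-,+,-,+,-,+,+
SVMPIII-2,+,+,-,+,-,+,+,+,+,+
SVMPIII-3,+,+,+,+,+,+,+,+,+,+
SVMPIII-4,+,+,+,+,+,+,+,+,+,+
SVMPIII-5,+,-,+,+,+,+,+,+,+,+
SVMPIII-6,+,-,+,+,+,+,+,-,+,+
SVMPIII-7,+,+,+,+,+,+,+,-,+,+
SVMPIII-8,+,+,+,+,+,+,+,+,+,+
SVMPIII-9,+,+,+,+,+,+,+,+,+,+
SVMPIII-10,+,+,+,+,+,+,+,+,+,+
SVSP-1,+,+,+,+,+,+,+,+,+,+
SVSP-2,+,+,+,+,+,+,+,+,+,+
SVSP-3,+,+,+,+,+,+,+,+,-,-
SVSP-4,+,+,+,+,+,+,+,+,+,+
SVSP-5,+,+,+,+,+,+,+,+,+,+
SVSP-6,+,+,+,+,+,+,+,+,+,+
SVSP-7,+,+,+,-,+,+,+,-,+,+
SVSP-8,+,+,+,-,+,+,+,-,+,+
SVSP-9,+,-,+,+,+,+,+,+,+,+
SVSP-10,+,+,+,+,+,+,+,+,+,+
SVSP-11,+,+,+,+,+,+,+,+,+,+
SVSP-12,+,+,+,+,+,+,+,-,+,+
VEGF-1,+,+,+,+,+,+,+,+,+,+
VEGF-2,+,+,+,+,+,+,+,+,+,+
Vespryn-1,+,+,+,+,+,+,+,+,+,+
# Absent,3,8,1,8,5,5,3,14,5,2
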