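Toxin	ANF	BR	CAL	ENP	LSG
3FTx-1	down	none	none	none	up
3FTx-2	down	none	up	down	up
BPP-1	up	up	up	none	up
CRISP-1	none	up	none	none	none
CTL-1	none	none	none	none	none
CTL-2	none	none	none	none	none
CTL-3	none	none	none	none	none
CTL-4	none	none	none	none	none
CTL-5	none	none	none	none	none
CTL-6	none	none	none	none	none
CTL-7	none	down	none	none	none
CTL-8	none	none	none	none	none
CTL-9	none	none	none	none	none
CTL-10	none	none	none	none	none
CTL-11	none	none	down	down	none
CTL-12	down	none	none	down	up
CTL-13	down	down	down	none	none
HYAL-1	down	none	none	none	none
KUN-1	none	none	none	none	none
KUN-2	none	none	none	none	none
LAAO-1	none	none	up	none	none
MYO-1	none	none	none	up	none
MYO-2	none	none	down	none	none
NGF-1	up	up	up	up	up
NUC-1	none	none	none	none	none
PDE-1	none	none	none	none	none
PLA2-1	none	none	none	none	none
PLA2-2	up	none	up	none	up
PLB-1	none	none	up	none	none
SVMPII-1	up	up	up	none	none
SVMPII-2	none	none	none	down	none
SVMPII-3	up	up	up	none	up
SVMPII-4	down	down	down	down	down
SVMPII-5	up	none	none	none	none
SVMPIII-1	up	up	up	none	up
SVMPIII-2	down	down	down	down	down
SVMPIII-3	none	none	none	none	none
SVMPIII-4	down	none	none	down	down
SVMPIII-5	up	up	up	down	up
SVMPIII-6	up	up	up	none	up
SVMPIII-7	up	none	up	none	up
SVMPIII-8	none	none	none	down	none
SVMPIII-9	none	none	none	none	none
SVMPIII-10	none	none	none	none	none
SVSP-1	up	none	none	none	none
SVSP-2	none	none	none	none	none
SVSP-3	none	none	none	none	none
SVSP-4	none	none	none	none	none
SVSP-5	none	none	none	none	none
SVSP-6	up	none	up	none	up
SVSP-7	up	none	up	none	up
SVSP-8	up	none	up	none	up
SVSP-9	up	none	up	none	up
SVSP-10	none	none	none	none	none
SVSP-11	up	none	up	none	none
SVSP-12	none	none	up	none	none
VEGF-1	none	none	none	none	none
VEGF-2	none	none	none	none	none
Vespryn-1	none	none	none	none	none
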