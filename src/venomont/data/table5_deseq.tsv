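Toxin	adjusted_p	log2_fold_change
3FTx-1	>0.1	-1.82
3FTx-2	>0.1	-2.09
BPP-1	1.8e-3	-3.55
CRISP-1	>0.1	-1.85
CTL-1	>0.1	0.77
CTL-2	>0.1	0.81
CTL-3	>0.1	0.97
CTL-4	>0.1	0.81
CTL-5	>0.1	0.83
CTL-6	>0.1	-0.02
CTL-7	>0.1	1.67
CTL-8	>0.1	0.77
CTL-9	>0.1	0.68
CTL-10	>0.1	0.05
CTL-11	>0.1	1.45
CTL-12	>0.1	-1.14
CTL-13	>0.1	3.08
HYAL-1	>0.1	0.43
KUN-1	>0.1	-0.28
KUN-2	>0.1	0.15
LAAO-1	>0.1	-0.37
MYO-1	>0.1	0.52
MYO-2	>0.1	-0.15
NGF-1	9.3e-13	-4.54
NUC-1	>0.1	0.34
PDE-1	>0.1	0.85
PLA2-1	9.4e-2	1.39
PLA2-2	7.1e-2	-3.87
PLB-1	>0.1	-0.87
SVMPII-1	>0.1	-3.02
SVMPII-2	>0.1	0.69
SVMPII-3	9.4e-2	-2.75
SVMPII-4	7.8e-7	5.33
SVMPII-5	>0.1	-2.10
SVMPIII-1	9.4e-2	-3.23
SVMPIII-2	9.7e-6	2.65
SVMPIII-3	>0.1	0.11
SVMPIII-4	>0.1	2.96
SVMPIII-5	>0.1	-2.68
SVMPIII-6	9.4e-2	-4.70
SVMPIII-7	>0.1	-1.19
SVMPIII-8	>0.1	0.36
SVMPIII-9	>0.1	1.39
SVMPIII-10	>0.1	0.42
SVSP-1	>0.1	-0.59
SVSP-2	>0.1	-0.61
SVSP-3	>0.1	-1.75
SVSP-4	>0.1	-0.60
SVSP-5	>0.1	-0.53
SVSP-6	>0.1	-2.00
SVSP-7	>0.1	-1.50
SVSP-8	4.8e-2	-1.32
SVSP-9	2.3e-2	-3.40
SVSP-10	>0.1	-2.39
SVSP-11	>0.1	-1.72
SVSP-12	>0.1	-2.01
VEGF-1	>0.1	0.79
VEGF-2	>0.1	-0.23
Vespryn-1	>0.1	-0.07
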