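Toxin	adjusted_p	log2_fold_change
3FTx-1	NA	-0.08
3FTx-2	NA	-0.12
BPP-1	8.3e-2	-0.83
CRISP-1	2.7e-2	-1.07
CTL-1	>0.1	0.55
CTL-2	>0.1	0.63
CTL-3	>0.1	0.71
CTL-4	>0.1	0.64
CTL-5	>0.1	0.66
CTL-6	>0.1	-0.02
CTL-7	2.9e-2	1.04
CTL-8	>0.1	0.53
CTL-9	>0.1	0.49
CTL-10	>0.1	0.03
CTL-11	2.7e-2	1.01
CTL-12	>0.1	-0.18
CTL-13	>0.1	0.65
HYAL-1	>0.1	0.23
KUN-1	>0.1	-0.26
KUN-2	>0.1	0.15
LAAO-1	>0.1	-0.12
MYO-1	>0.1	0.18
MYO-2	>0.1	-0.02
NGF-1	2.0e-2	-1.05
NUC-1	>0.1	0.26
PDE-1	>0.1	0.64
PLA2-1	2.8e-2	0.98
PLA2-2	1.3e-2	-1.14
PLB-1	>0.1	-0.51
SVMPII-1	>0.1	-0.52
SVMPII-2	>0.1	0.48
SVMPII-3	>0.1	-0.75
SVMPII-4	3.2e-2	0.94
SVMPII-5	>0.1	-0.68
SVMPIII-1	>0.1	-0.68
SVMPIII-2	2.3e-8	1.90
SVMPIII-3	>0.1	0.08
SVMPIII-4	7.9e-4	1.46
SVMPIII-5	>0.1	-0.58
SVMPIII-6	8.3e-4	-1.40
SVMPIII-7	>0.1	-0.64
SVMPIII-8	>0.1	0.21
SVMPIII-9	9.8e-2	0.87
SVMPIII-10	>0.1	0.23
SVSP-1	>0.1	-0.34
SVSP-2	>0.1	-0.33
SVSP-3	2.5e-2	-1.08
SVSP-4	>0.1	-0.32
SVSP-5	>0.1	-0.28
SVSP-6	>0.1	-0.44
SVSP-7	5.1e-2	-0.96
SVSP-8	>0.1	-0.81
SVSP-9	>0.1	-0.45
SVSP-10	3.7e-2	-1.04
SVSP-11	>0.1	-0.54
SVSP-12	>0.1	-0.45
VEGF-1	2.6e-2	0.70
VEGF-2	>0.1	-0.14
Vespryn-1	>0.1	-0.05
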