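tf	lc	bc	lk
ZBTB16	9	4	3
KLF4	9	4	1
TAL1	9	3	2
FOXM1	9	2	1
BZW2	9	1	1
HLF	8	3	1
GPRASP1	8	2	2
MNDA	8	2	1
PKNOX2	8	1	1
TFAP2C	8	1	1
SOX4	10	1	2
EGR1	7	4	3
FOSB	7	4	1
SOX17	10	3	0
EPAS1	8	3	0
KLF2	8	3	0
ID4	8	3	0
MEIS1	8	2	0
MYBL2	8	2	0
NR2F1	8	2	0
DLX5	8	1	0
TBX5	8	1	0
NR4A3	8	0	1
ID2	7	0	3
ETV4	7	0	1
SOX12	7	0	1
TCF3	7	0	1
RORA	6	0	2
FOXF1	8	0	0
HOXC6	8	0	0
RFX2	8	0	0
GATA6	7	0	0
RARA	7	0	0
PAX9	7	0	0
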