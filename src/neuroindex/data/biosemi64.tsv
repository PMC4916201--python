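Fp1	0
AF7	1
AF3	2
F1	3
F3	4
F5	5
F7	6
FT7	7
FC5	8
FC3	9
FC1	10
C1	11
C3	12
C5	13
T7	14
TP7	15
CP5	16
CP3	17
CP1	18
P1	19
P3	20
P5	21
P7	22
P9	23
PO7	24
PO3	25
O1	26
Iz	27
Oz	28
POz	29
Pz	30
CPz	31
Fpz	32
Fp2	33
AF8	34
AF4	35
AFz	36
Fz	37
F2	38
F4	39
F6	40
F8	41
FT8	42
FC6	43
FC4	44
FC2	45
FCz	46
Cz	47
C2	48
C4	49
C6	50
T8	51
TP8	52
CP6	53
CP4	54
CP2	55
P2	56
P4	57
P6	58
P8	59
P10	60
PO8	61
PO4	62
O2	63
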