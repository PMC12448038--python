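label	x	y
FP1	-0.309	0.951
FPZ	0.000	1.000
FP2	0.309	0.951
F7	-0.770	0.560
F3	-0.390	0.450
FZ	0.000	0.400
F4	0.390	0.450
F8	0.770	0.560
M1	-0.920	-0.380
T7	-1.000	0.000
C3	-0.400	0.000
CZ	0.000	0.000
C4	0.400	0.000
T8	1.000	0.000
M2	0.920	-0.380
P7	-0.805	-0.588
P3	-0.390	-0.450
PZ	0.000	-0.400
P4	0.390	-0.450
P8	0.805	-0.588
POZ	0.000	-0.720
O1	-0.309	-0.951
OZ	0.000	-1.000
O2	0.309	-0.951
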