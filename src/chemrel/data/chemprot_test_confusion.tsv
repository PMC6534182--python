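gold\pred	NEG	CPR:3	CPR:4	CPR:5	CPR:6	CPR:9
NEG	10267	164	415	32	51	84
CPR:3	220	358	80	3	2	1
CPR:4	427	14	1216	0	1	3
CPR:5	66	2	3	115	8	0
CPR:6	77	0	3	6	195	0
CPR:9	386	3	10	0	0	244
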