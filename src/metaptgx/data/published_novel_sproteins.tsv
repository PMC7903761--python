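candidate	species	source	size_aa	trypsin_peptides	trypsin_psms	aspn_peptides	aspn_psms
AC1	A. caccae	prodigal	47	1	5	2	11
AC2	A. caccae	prodigal	49	1	5	0	0
AC3	A. caccae	prodigal	57	3	25	0	0
BL1	B. longum	insilico	57	1	5	0	0
BP1	B. producta	prodigal	39	4	12	2	8
BP2	B. producta	prodigal	45	1	5	0	0
BP3	B. producta	prodigal	45	1	19	0	0
BP4	B. producta	prodigal	46	3	12	2	20
BP5	B. producta	prodigal	48	1	11	0	0
BP6	B. producta	prodigal	49	4	25	0	0
BP7	B. producta	prodigal	52	2	9	2	4
BP8	B. producta	prodigal	57	2	12	2	3
BP9	B. producta	prodigal	58	3	23	0	0
BP10	B. producta	prodigal	61	2	50	4	209
BP11	B. producta	prodigal	64	2	6	0	0
BP12	B. producta	prodigal	66	5	34	4	11
BP13	B. producta	prodigal	70	6	547	5	405
BP14	B. producta	chemgenome	81	6	55	2	5
BP15	B. producta	chemgenome	87	0	0	1	4
BT1	B. thetaiotaomicron	chemgenome	32	1	5	0	0
BT2	B. thetaiotaomicron	prodigal	36	0	0	1	16
BT3	B. thetaiotaomicron	prodigal	53	2	3	0	0
BT4	B. thetaiotaomicron	prodigal	55	1	19	1	4
BT5	B. thetaiotaomicron	insilico	57	4	30	2	10
BT6	B. thetaiotaomicron	prodigal	57	3	115	5	36
BT7	B. thetaiotaomicron	prodigal	61	1	8	2	19
BT8	B. thetaiotaomicron	prodigal	68	2	35	0	0
CR1	C. ramosum	insilico	20	1	4	0	0
CR2	C. ramosum	insilico	31	2	18	0	0
CR3	C. ramosum	prodigal	44	0	0	1	3
CR4	C. ramosum	prodigal	58	7	53	3	13
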