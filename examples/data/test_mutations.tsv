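Gene name	Mutation AA	Position	Source	Sample name
BRAF	p.A600I		TEST	TEST_S00001
BRAF	p.A600_D602del		TEST	TEST_S00002
BRAF	p.A600fs*10		TEST	TEST_S00003
BRAF	p.A600*		TEST	TEST_S00004
TP53	p.Q273_R274insA		TEST	TEST_S00005
TP53	p.Q273dup		TEST	TEST_S00006
TP53	p.Q273A		TEST	TEST_S00007
PTEN	p.M130_P132del		TEST	TEST_S00008
PTEN	p.M130fs*7		TEST	TEST_S00009
PTEN	p.M130*		TEST	TEST_S00010
EGFR	p.H746_I747insQ		TEST	TEST_S00011
EGFR	p.H746dup		TEST	TEST_S00012
EGFR	p.H746Q		TEST	TEST_S00013
NFE2L2	p.L29_N31del		TEST	TEST_S00014
NFE2L2	p.L29fs*4		TEST	TEST_S00015
NFE2L2	p.Y79*		TEST	TEST_S00016
NFE2L2	p.Y79_A80insH		TEST	TEST_S00017
CTNNB1	p.C41dup		TEST	TEST_S00018
CTNNB1	p.C41K		TEST	TEST_S00019
IDH1	p.P132_R134del		TEST	TEST_S00020
TP53	p.D22fs*4		TEST	TEST_S00021
PTEN	p.F364dup		TEST	TEST_S00022
PTEN	p.G385P		TEST	TEST_S00023
PTEN	p.H346_K348del		TEST	TEST_S00024
CTNNB1	p.F504fs*7		TEST	TEST_S00025
CTNNB1	p.N631*		TEST	TEST_S00026
CTNNB1	p.M230_N231insV		TEST	TEST_S00027
NFE2L2	p.V577_Y579del		TEST	TEST_S00028
NFE2L2	p.H146fs*4		TEST	TEST_S00029
NFE2L2	p.R214*		TEST	TEST_S00030
BRAF	p.T356E		TEST	TEST_S00031
BRAF	p.A480_D482del		TEST	TEST_S00032
BRAF	p.C201fs*10		TEST	TEST_S00033
BRAF	p.S135*		TEST	TEST_S00034
IDH1	p.E23_F24insM		TEST	TEST_S00035
IDH1	p.R74dup		TEST	TEST_S00036
IDH1	p.F164N		TEST	TEST_S00037
IDH1	p.N231_Q233del		TEST	TEST_S00038
KIT	p.K908fs*7		TEST	TEST_S00039
KIT	p.I787*		TEST	TEST_S00040
EGFR	p.N231_Q233del		TEST	TEST_S00041
EGFR	p.F504fs*4		TEST	TEST_S00042
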