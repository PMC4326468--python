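# Synthetic hg18-style cytoband fixture for chr1/chr2 (UCSC cytoBand.txt dialect).
# Band names and order follow the human ISCN ideogram; boundaries are
# approximate reconstructions, not the genuine hg18 track.
chr1	0	2300000	p36.33	gneg
chr1	2300000	5400000	p36.32	gneg
chr1	5400000	7200000	p36.31	gneg
chr1	7200000	9200000	p36.23	gneg
chr1	9200000	12700000	p36.22	gneg
chr1	12700000	16100000	p36.21	gneg
chr1	16100000	20300000	p36.13	gneg
chr1	20300000	23300000	p36.12	gneg
chr1	23300000	28000000	p36.11	gneg
chr1	28000000	30200000	p35.3	gneg
chr1	30200000	32400000	p35.2	gneg
chr1	32400000	34600000	p35.1	gneg
chr1	34600000	40100000	p34.3	gneg
chr1	40100000	44100000	p34.2	gneg
chr1	44100000	46800000	p34.1	gneg
chr1	46800000	50700000	p33	gneg
chr1	50700000	56100000	p32.3	gneg
chr1	56100000	59000000	p32.2	gneg
chr1	59000000	61300000	p32.1	gneg
chr1	61300000	68900000	p31.3	gneg
chr1	68900000	69700000	p31.2	gneg
chr1	69700000	84900000	p31.1	gneg
chr1	84900000	88300000	p22.3	gneg
chr1	88300000	91800000	p22.2	gneg
chr1	91800000	94700000	p22.1	gneg
chr1	94700000	99700000	p21.3	gneg
chr1	99700000	102200000	p21.2	gneg
chr1	102200000	107200000	p21.1	gneg
chr1	107200000	111800000	p13.3	gneg
chr1	111800000	116100000	p13.2	gneg
chr1	116100000	117800000	p13.1	gneg
chr1	117800000	120500000	p12	gneg
chr1	120500000	121100000	p11.2	gneg
chr1	121100000	124300000	p11.1	acen
chr1	124300000	128000000	q11	acen
chr1	128000000	142400000	q12	gneg
chr1	142400000	148000000	q21.1	gneg
chr1	148000000	149600000	q21.2	gneg
chr1	149600000	153300000	q21.3	gneg
chr1	153300000	154900000	q22	gneg
chr1	154900000	156500000	q23.1	gneg
chr1	156500000	157900000	q23.2	gneg
chr1	157900000	160800000	q23.3	gneg
chr1	160800000	163200000	q24.1	gneg
chr1	163200000	165500000	q24.2	gneg
chr1	165500000	169600000	q24.3	gneg
chr1	169600000	170900000	q25.1	gneg
chr1	170900000	172900000	q25.2	gneg
chr1	172900000	184000000	q25.3	gneg
chr1	184000000	190800000	q31.1	gneg
chr1	190800000	193800000	q31.2	gneg
chr1	193800000	198700000	q31.3	gneg
chr1	198700000	205100000	q32.1	gneg
chr1	205100000	208900000	q32.2	gneg
chr1	208900000	211500000	q32.3	gneg
chr1	211500000	218100000	q41	gneg
chr1	218100000	219800000	q42.11	gneg
chr1	219800000	221500000	q42.12	gneg
chr1	221500000	224100000	q42.13	gneg
chr1	224100000	226300000	q42.2	gneg
chr1	226300000	230500000	q42.3	gneg
chr1	230500000	239100000	q43	gneg
chr1	239100000	247249719	q44	gneg
chr2	0	4300000	p25.3	gneg
chr2	4300000	7000000	p25.2	gneg
chr2	7000000	12800000	p25.1	gneg
chr2	12800000	17000000	p24.3	gneg
chr2	17000000	19100000	p24.2	gneg
chr2	19100000	23900000	p24.1	gneg
chr2	23900000	27700000	p23.3	gneg
chr2	27700000	29800000	p23.2	gneg
chr2	29800000	31800000	p23.1	gneg
chr2	31800000	36300000	p22.3	gneg
chr2	36300000	38300000	p22.2	gneg
chr2	38300000	41500000	p22.1	gneg
chr2	41500000	47500000	p21	gneg
chr2	47500000	52600000	p16.3	gneg
chr2	52600000	54700000	p16.2	gneg
chr2	54700000	61000000	p16.1	gneg
chr2	61000000	63900000	p15	gneg
chr2	63900000	68900000	p14	gneg
chr2	68900000	71300000	p13.3	gneg
chr2	71300000	73300000	p13.2	gneg
chr2	73300000	74800000	p13.1	gneg
chr2	74800000	83100000	p12	gneg
chr2	83100000	91000000	p11.2	gneg
chr2	91000000	93300000	p11.1	acen
chr2	93300000	95700000	q11.1	acen
chr2	95700000	102100000	q11.2	gneg
chr2	102100000	105300000	q12.1	gneg
chr2	105300000	106700000	q12.2	gneg
chr2	106700000	108600000	q12.3	gneg
chr2	108600000	112800000	q13	gneg
chr2	112800000	118100000	q14.1	gneg
chr2	118100000	121900000	q14.2	gneg
chr2	121900000	129900000	q14.3	gneg
chr2	129900000	132500000	q21.1	gneg
chr2	132500000	134700000	q21.2	gneg
chr2	134700000	136800000	q21.3	gneg
chr2	136800000	142400000	q22.1	gneg
chr2	142400000	144100000	q22.2	gneg
chr2	144100000	148600000	q22.3	gneg
chr2	148600000	149300000	q23.1	gneg
chr2	149300000	149900000	q23.2	gneg
chr2	149900000	154300000	q23.3	gneg
chr2	154300000	158800000	q24.1	gneg
chr2	158800000	163700000	q24.2	gneg
chr2	163700000	169700000	q24.3	gneg
chr2	169700000	177900000	q31.1	gneg
chr2	177900000	179700000	q31.2	gneg
chr2	179700000	184900000	q31.3	gneg
chr2	184900000	191000000	q32.1	gneg
chr2	191000000	193400000	q32.2	gneg
chr2	193400000	198300000	q32.3	gneg
chr2	198300000	204400000	q33.1	gneg
chr2	204400000	206000000	q33.2	gneg
chr2	206000000	210200000	q33.3	gneg
chr2	210200000	215200000	q34	gneg
chr2	215200000	221500000	q35	gneg
chr2	221500000	225400000	q36.1	gneg
chr2	225400000	226700000	q36.2	gneg
chr2	226700000	230700000	q36.3	gneg
chr2	230700000	234500000	q37.1	gneg
chr2	234500000	236400000	q37.2	gneg
chr2	236400000	242951149	q37.3	gneg
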