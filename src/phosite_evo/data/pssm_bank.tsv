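kinase	acceptor_class	offset	residue	weight
pro_directed_01	ST	-4	L	0.91
pro_directed_01	ST	-2	P	1.3
pro_directed_01	ST	1	P	2.53
pro_directed_01	ST	2	G	-0.6
pro_directed_01	ST	3	K	1.28
pro_directed_01	ST	3	R	-0.6
pro_directed_02	ST	-5	I	-0.6
pro_directed_02	ST	-3	L	0.76
pro_directed_02	ST	1	P	2.2
pro_directed_02	ST	5	G	-0.6
pro_directed_03	ST	-5	F	-0.6
pro_directed_03	ST	-5	H	-0.6
pro_directed_03	ST	-2	P	1.54
pro_directed_03	ST	1	P	2.51
pro_directed_03	ST	2	L	0.67
pro_directed_04	ST	-4	E	-0.6
pro_directed_04	ST	-1	R	-0.6
pro_directed_04	ST	1	P	2.19
pro_directed_04	ST	3	K	1.32
pro_directed_04	ST	4	L	0.66
pro_directed_05	ST	-4	L	0.93
pro_directed_05	ST	-2	M	-0.6
pro_directed_05	ST	-2	P	1.65
pro_directed_05	ST	1	P	2.35
pro_directed_05	ST	3	E	-0.6
pro_directed_06	ST	-3	L	0.9
pro_directed_06	ST	-3	W	-0.6
pro_directed_06	ST	1	P	2.05
pro_directed_06	ST	4	A	-0.6
pro_directed_07	ST	-2	A	-0.6
pro_directed_07	ST	-2	P	1.57
pro_directed_07	ST	1	P	2.33
pro_directed_07	ST	2	L	0.84
pro_directed_07	ST	3	K	1.39
pro_directed_07	ST	3	T	-0.6
pro_directed_08	ST	-3	S	-0.6
pro_directed_08	ST	1	P	2.5
pro_directed_08	ST	3	D	-0.6
pro_directed_08	ST	4	L	0.7
pro_directed_09	ST	-4	L	0.66
pro_directed_09	ST	-2	P	1.23
pro_directed_09	ST	1	P	2.33
pro_directed_09	ST	5	D	-0.6
pro_directed_09	ST	5	I	-0.6
pro_directed_10	ST	-3	L	0.89
pro_directed_10	ST	-1	Y	-0.6
pro_directed_10	ST	1	P	2.19
pro_directed_10	ST	2	L	-0.6
pro_directed_10	ST	3	K	0.95
basophilic_01	ST	-5	R	1.13
basophilic_01	ST	-3	R	2.07
basophilic_01	ST	-2	R	1.61
basophilic_01	ST	2	F	1.01
basophilic_01	ST	3	W	-0.6
basophilic_01	ST	5	W	-0.6
basophilic_02	ST	-3	R	2.22
basophilic_02	ST	-2	K	1.64
basophilic_02	ST	-1	G	-0.6
basophilic_02	ST	3	E	-0.6
basophilic_03	ST	-5	R	1.03
basophilic_03	ST	-3	R	2.11
basophilic_03	ST	-2	R	1.8
basophilic_03	ST	-1	M	-0.6
basophilic_03	ST	5	S	-0.6
basophilic_04	ST	-3	N	-0.6
basophilic_04	ST	-3	R	2.05
basophilic_04	ST	-2	K	1.83
basophilic_04	ST	-2	M	-0.6
basophilic_04	ST	2	F	0.9
basophilic_05	ST	-5	H	-0.6
basophilic_05	ST	-5	R	0.83
basophilic_05	ST	-3	R	2.04
basophilic_05	ST	-2	R	1.46
basophilic_05	ST	-2	V	-0.6
basophilic_06	ST	-4	E	-0.6
basophilic_06	ST	-3	R	2.29
basophilic_06	ST	-2	G	-0.6
basophilic_06	ST	-2	K	1.65
basophilic_07	ST	-5	R	1.02
basophilic_07	ST	-3	R	2.04
basophilic_07	ST	-2	R	1.89
basophilic_07	ST	2	F	0.7
basophilic_07	ST	2	W	-0.6
basophilic_07	ST	5	M	-0.6
basophilic_08	ST	-3	R	2.23
basophilic_08	ST	-2	K	1.68
basophilic_08	ST	1	S	-0.6
basophilic_08	ST	5	E	-0.6
basophilic_09	ST	-5	R	0.94
basophilic_09	ST	-3	R	2.26
basophilic_09	ST	-2	R	1.79
basophilic_09	ST	-1	R	-0.6
basophilic_09	ST	2	K	-0.6
basophilic_10	ST	-3	R	2.31
basophilic_10	ST	-2	K	1.97
basophilic_10	ST	2	D	-0.6
basophilic_10	ST	2	F	0.66
basophilic_10	ST	2	N	-0.6
acidophilic_01	ST	-1	E	0.75
acidophilic_01	ST	1	D	1.67
acidophilic_01	ST	2	D	0.99
acidophilic_01	ST	3	E	1.89
acidophilic_01	ST	3	I	-0.6
acidophilic_02	ST	-2	H	-0.6
acidophilic_02	ST	1	E	1.75
acidophilic_02	ST	1	T	-0.6
acidophilic_02	ST	2	D	1.1
acidophilic_02	ST	3	E	1.65
acidophilic_03	ST	-1	E	0.68
acidophilic_03	ST	1	D	1.73
acidophilic_03	ST	2	D	0.9
acidophilic_03	ST	3	E	1.52
acidophilic_03	ST	4	D	-0.6
acidophilic_03	ST	5	N	-0.6
acidophilic_04	ST	-4	R	-0.6
acidophilic_04	ST	1	E	1.63
acidophilic_04	ST	2	D	1.01
acidophilic_04	ST	2	E	-0.6
acidophilic_04	ST	3	E	1.77
acidophilic_05	ST	-5	K	-0.6
acidophilic_05	ST	-1	E	0.81
acidophilic_05	ST	1	D	1.55
acidophilic_05	ST	2	D	0.88
acidophilic_05	ST	3	E	1.54
acidophilic_06	ST	1	E	1.7
acidophilic_06	ST	2	D	1.03
acidophilic_06	ST	2	K	-0.6
acidophilic_06	ST	3	E	1.87
acidophilic_06	ST	5	L	-0.6
acidophilic_07	ST	-5	L	-0.6
acidophilic_07	ST	-3	C	-0.6
acidophilic_07	ST	-1	E	0.73
acidophilic_07	ST	1	D	1.59
acidophilic_07	ST	2	D	0.83
acidophilic_07	ST	3	E	1.48
acidophilic_08	ST	-5	N	-0.6
acidophilic_08	ST	-2	G	-0.6
acidophilic_08	ST	1	E	1.8
acidophilic_08	ST	2	D	0.87
acidophilic_08	ST	3	E	1.72
acidophilic_09	ST	-5	T	-0.6
acidophilic_09	ST	-1	E	0.73
acidophilic_09	ST	1	D	1.67
acidophilic_09	ST	2	D	1.32
acidophilic_09	ST	3	E	1.46
acidophilic_09	ST	3	L	-0.6
acidophilic_10	ST	-5	R	-0.6
acidophilic_10	ST	1	E	1.9
acidophilic_10	ST	2	D	0.89
acidophilic_10	ST	3	E	1.93
acidophilic_10	ST	5	V	-0.6
tyr_kinase_01	Y	-3	D	1.83
tyr_kinase_01	Y	-2	Q	-0.6
tyr_kinase_01	Y	-1	E	1.07
tyr_kinase_01	Y	1	E	0.75
tyr_kinase_01	Y	3	I	1.71
tyr_kinase_01	Y	5	Q	-0.6
tyr_kinase_02	Y	-3	E	1.63
tyr_kinase_02	Y	-2	G	-0.6
tyr_kinase_02	Y	-1	E	1.23
tyr_kinase_02	Y	3	V	1.96
tyr_kinase_02	Y	4	C	-0.6
tyr_kinase_03	Y	-4	A	-0.6
tyr_kinase_03	Y	-3	D	1.99
tyr_kinase_03	Y	-1	E	1.58
tyr_kinase_03	Y	1	E	0.69
tyr_kinase_03	Y	3	L	1.43
tyr_kinase_03	Y	5	L	-0.6
tyr_kinase_04	Y	-3	E	1.86
tyr_kinase_04	Y	-1	E	1.38
tyr_kinase_04	Y	1	N	-0.6
tyr_kinase_04	Y	1	V	-0.6
tyr_kinase_04	Y	3	I	1.7
tyr_kinase_05	Y	-3	D	1.43
tyr_kinase_05	Y	-3	K	-0.6
tyr_kinase_05	Y	-1	E	1.56
tyr_kinase_05	Y	1	E	1.11
tyr_kinase_05	Y	3	V	1.54
tyr_kinase_05	Y	5	F	-0.6
tyr_kinase_06	Y	-3	E	1.67
tyr_kinase_06	Y	-2	H	-0.6
tyr_kinase_06	Y	-1	E	1.42
tyr_kinase_06	Y	3	L	1.67
tyr_kinase_06	Y	5	R	-0.6
tyr_kinase_07	Y	-3	D	1.78
tyr_kinase_07	Y	-1	E	1.24
tyr_kinase_07	Y	1	E	0.71
tyr_kinase_07	Y	3	I	1.89
tyr_kinase_07	Y	3	R	-0.6
tyr_kinase_07	Y	4	L	-0.6
tyr_kinase_08	Y	-5	C	-0.6
tyr_kinase_08	Y	-3	C	-0.6
tyr_kinase_08	Y	-3	E	1.5
tyr_kinase_08	Y	-1	E	1.6
tyr_kinase_08	Y	3	V	1.9
tyr_kinase_09	Y	-3	D	1.95
tyr_kinase_09	Y	-1	E	1.13
tyr_kinase_09	Y	1	E	0.78
tyr_kinase_09	Y	3	L	1.63
tyr_kinase_09	Y	4	G	-0.6
tyr_kinase_09	Y	4	T	-0.6
tyr_kinase_10	Y	-4	F	-0.6
tyr_kinase_10	Y	-3	E	1.89
tyr_kinase_10	Y	-1	E	1.0
tyr_kinase_10	Y	3	I	1.55
tyr_kinase_10	Y	5	N	-0.6
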