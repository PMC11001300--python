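position_label	residue	pA	pC	pG	pT
-1	R	0.050000	0.050000	0.850000	0.050000
-1	K	0.125000	0.125000	0.500000	0.250000
-1	H	0.150000	0.125000	0.600000	0.125000
-1	N	0.800000	0.066667	0.066667	0.066667
-1	Q	0.700000	0.100000	0.100000	0.100000
-1	D	0.150000	0.600000	0.125000	0.125000
-1	E	0.250000	0.500000	0.125000	0.125000
-1	S	0.200000	0.200000	0.200000	0.400000
-1	T	0.200000	0.150000	0.150000	0.500000
-1	A	0.300000	0.200000	0.200000	0.300000
-1	V	0.250000	0.175000	0.175000	0.400000
-1	L	0.200000	0.200000	0.200000	0.400000
-1	I	0.200000	0.200000	0.200000	0.400000
-1	M	0.350000	0.200000	0.200000	0.250000
-1	Y	0.200000	0.250000	0.200000	0.350000
2	R	0.050000	0.050000	0.850000	0.050000
2	K	0.125000	0.125000	0.500000	0.250000
2	H	0.150000	0.125000	0.600000	0.125000
2	N	0.800000	0.066667	0.066667	0.066667
2	Q	0.700000	0.100000	0.100000	0.100000
2	D	0.150000	0.600000	0.125000	0.125000
2	E	0.250000	0.500000	0.125000	0.125000
2	S	0.200000	0.200000	0.200000	0.400000
2	T	0.200000	0.150000	0.150000	0.500000
2	A	0.300000	0.200000	0.200000	0.300000
2	V	0.250000	0.175000	0.175000	0.400000
2	L	0.200000	0.200000	0.200000	0.400000
2	I	0.200000	0.200000	0.200000	0.400000
2	M	0.350000	0.200000	0.200000	0.250000
2	Y	0.200000	0.250000	0.200000	0.350000
3	R	0.050000	0.050000	0.850000	0.050000
3	K	0.125000	0.125000	0.500000	0.250000
3	H	0.150000	0.125000	0.600000	0.125000
3	N	0.800000	0.066667	0.066667	0.066667
3	Q	0.700000	0.100000	0.100000	0.100000
3	D	0.150000	0.600000	0.125000	0.125000
3	E	0.250000	0.500000	0.125000	0.125000
3	S	0.200000	0.200000	0.200000	0.400000
3	T	0.200000	0.150000	0.150000	0.500000
3	A	0.300000	0.200000	0.200000	0.300000
3	V	0.250000	0.175000	0.175000	0.400000
3	L	0.200000	0.200000	0.200000	0.400000
3	I	0.200000	0.200000	0.200000	0.400000
3	M	0.350000	0.200000	0.200000	0.250000
3	Y	0.200000	0.250000	0.200000	0.350000
6	R	0.050000	0.050000	0.850000	0.050000
6	K	0.125000	0.125000	0.500000	0.250000
6	H	0.150000	0.125000	0.600000	0.125000
6	N	0.800000	0.066667	0.066667	0.066667
6	Q	0.700000	0.100000	0.100000	0.100000
6	D	0.150000	0.600000	0.125000	0.125000
6	E	0.250000	0.500000	0.125000	0.125000
6	S	0.200000	0.200000	0.200000	0.400000
6	T	0.200000	0.150000	0.150000	0.500000
6	A	0.300000	0.200000	0.200000	0.300000
6	V	0.250000	0.175000	0.175000	0.400000
6	L	0.200000	0.200000	0.200000	0.400000
6	I	0.200000	0.200000	0.200000	0.400000
6	M	0.350000	0.200000	0.200000	0.250000
6	Y	0.200000	0.250000	0.200000	0.350000
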