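# Isotopic masses (Da) and natural abundances, CODATA/IUPAC values.
# One row per stable isotope; the most abundant isotope of each element is
# taken as the monoisotopic (principal) one.
element	mass	abundance
H	1.00782503207	0.999885
H	2.01410177812	0.000115
C	12.0	0.9893
C	13.00335483507	0.0107
N	14.0030740048	0.99636
N	15.0001088989	0.00364
O	15.9949146196	0.99757
O	16.9991317565	0.00038
O	17.9991596129	0.00205
S	31.97207100	0.9499
S	32.97145876	0.0075
S	33.96786690	0.0425
S	35.96708076	0.0001
P	30.97376163	1.0
Na	22.9897692809	1.0
F	18.99840322	1.0
Cl	34.96885268	0.7576
Cl	36.96590259	0.2424
K	38.96370668	0.932581
K	39.96399848	0.000117
K	40.96182576	0.067302
I	126.904473	1.0
Br	78.9183371	0.5069
Br	80.9162906	0.4931
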