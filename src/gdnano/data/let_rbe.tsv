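# Alpha-particle LET in tissue vs kinetic energy, and RBE (10% surviving
# fraction) vs LET, on a 1 MeV grid.
# E_MeV	LET_keV_per_um	RBE
1	200	2.4
2	140	3.7
3	130	4.5
4	110	4.3
5	100	4.3
6	90	4.3
7	80	4
8	70	3.5
9	60	3.3
10	55	3.2
11	54	3.1
12	53	3
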