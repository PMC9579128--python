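#source_label calibrated
#E_MeV SSB_per_alpha DSB_per_alpha
1 7.0566167181e+01 6.1000278046e+01
2 9.4280236079e+01 4.2209910480e+01
3 8.1815707160e+01 2.0680953764e+01
4 5.9500954410e+01 8.7971838712e+00
5 3.9279693476e+01 3.4632377493e+00
6 2.4390409825e+01 1.2982144046e+00
7 1.4518388739e+01 4.7046702904e-01
8 8.3788705298e+00 1.6632830086e-01
9 4.7227330935e+00 5.7702655447e-02
10 2.6128156964e+00 1.9722020687e-02
11 1.4238916483e+00 6.6599237040e-03
12 7.6637075339e-01 2.2267022538e-03
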