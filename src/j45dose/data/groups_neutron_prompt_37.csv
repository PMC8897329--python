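# energy group boundaries (MeV), log-spaced defaults; edit to swap in
# an alternative group structure (algorithms are boundary-agnostic)
# particle: neutron
edge_MeV
1.00000000e-09
1.89848083e-09
3.60422946e-09
6.84256054e-09
1.29904700e-08
2.46621583e-08
4.68206347e-08
8.88880774e-08
1.68752311e-07
3.20373027e-07
6.08222050e-07
1.15469790e-06
2.19217183e-06
4.16179620e-06
7.90109030e-06
1.50000685e-05
2.84773424e-05
5.40636887e-05
1.02638877e-04
1.94857940e-04
3.69934063e-04
7.02312726e-04
1.33332725e-03
2.53129622e-03
4.80561734e-03
9.12337240e-03
1.73205476e-02
3.28827276e-02
6.24272280e-02
1.18516896e-01
2.25002054e-01
4.27162086e-01
8.10959032e-01
1.53959018e+00
2.92288243e+00
5.54903627e+00
1.05347390e+01
2.00000000e+01
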