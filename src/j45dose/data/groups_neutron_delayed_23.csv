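# energy group boundaries (MeV), log-spaced defaults; edit to swap in
# an alternative group structure (algorithms are boundary-agnostic)
# particle: neutron
edge_MeV
1.00000000e-09
2.64054971e-09
6.97250278e-09
1.84112402e-08
4.86157950e-08
1.28372423e-07
3.38973766e-07
8.95077079e-07
2.36349552e-06
6.24092742e-06
1.64794791e-05
4.35148838e-05
1.14903214e-04
3.03407648e-04
8.01162978e-04
2.11551067e-03
5.58611109e-03
1.47504040e-02
3.89491751e-02
1.02847233e-01
2.71573232e-01
7.17102618e-01
1.89354511e+00
5.00000000e+00
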