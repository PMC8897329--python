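# energy group boundaries (MeV), log-spaced defaults; edit to swap in
# an alternative group structure (algorithms are boundary-agnostic)
# particle: gamma
edge_MeV
1.00000000e-02
1.38949549e-02
1.93069773e-02
2.68269580e-02
3.72759372e-02
5.17947468e-02
7.19685673e-02
1.00000000e-01
1.38949549e-01
1.93069773e-01
2.68269580e-01
3.72759372e-01
5.17947468e-01
7.19685673e-01
1.00000000e+00
1.38949549e+00
1.93069773e+00
2.68269580e+00
3.72759372e+00
5.17947468e+00
7.19685673e+00
1.00000000e+01
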