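# APPROXIMATE photon mass attenuation (mu_rho) and mass energy-absorption
# (muen_rho) coefficients, cm2/g, for testing-grade transport; magnitudes
# follow standard tissue/bone compilations but are NOT evaluated data.
medium,energy_MeV,mu_rho_cm2_g,muen_rho_cm2_g
soft_tissue,0.01,5.33,4.94
lung,0.01,5.33,4.94
soft_tissue,0.02,0.81,0.54
lung,0.02,0.81,0.54
soft_tissue,0.05,0.227,0.0419
lung,0.05,0.227,0.0419
soft_tissue,0.1,0.171,0.0256
lung,0.1,0.171,0.0256
soft_tissue,0.2,0.137,0.0297
lung,0.2,0.137,0.0297
soft_tissue,0.5,0.097,0.033
lung,0.5,0.097,0.033
soft_tissue,1.0,0.0708,0.0311
lung,1.0,0.0708,0.0311
soft_tissue,2.0,0.0494,0.0261
lung,2.0,0.0494,0.0261
soft_tissue,5.0,0.0303,0.0193
lung,5.0,0.0303,0.0193
soft_tissue,10.0,0.0222,0.0155
lung,10.0,0.0222,0.0155
soft_tissue,20.0,0.0181,0.0134
lung,20.0,0.0181,0.0134
skeleton,0.01,20.3,19.2
skeleton,0.02,2.75,2.16
skeleton,0.05,0.35,0.092
skeleton,0.1,0.18,0.0296
skeleton,0.2,0.132,0.0302
skeleton,0.5,0.0926,0.0316
skeleton,1.0,0.0676,0.0297
skeleton,2.0,0.0472,0.0248
skeleton,5.0,0.0295,0.0187
skeleton,10.0,0.0222,0.0157
skeleton,20.0,0.0185,0.0140
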