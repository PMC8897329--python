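# APPROXIMATE neutron total interaction coefficients (cm2/g) and tissue
# fluence-to-KERMA factors (Gy cm2) for testing-grade transport; the
# thermal 1/v capture rise and fast-recoil plateau are represented, but
# these are NOT evaluated nuclear data.
medium,energy_MeV,sigma_rho_cm2_g,kerma_Gy_cm2
soft_tissue,1e-09,6.0,1.2e-12
lung,1e-09,6.0,1.2e-12
soft_tissue,2.5e-08,2.1,2.4e-13
lung,2.5e-08,2.1,2.4e-13
soft_tissue,1e-06,1.6,4.0e-14
lung,1e-06,1.6,4.0e-14
soft_tissue,1e-04,1.2,1.5e-14
lung,1e-04,1.2,1.5e-14
soft_tissue,0.01,0.95,6.0e-13
lung,0.01,0.95,6.0e-13
soft_tissue,0.1,0.60,6.0e-12
lung,0.1,0.60,6.0e-12
soft_tissue,1.0,0.25,2.6e-11
lung,1.0,0.25,2.6e-11
soft_tissue,5.0,0.115,5.6e-11
lung,5.0,0.115,5.6e-11
soft_tissue,10.0,0.090,6.8e-11
lung,10.0,0.090,6.8e-11
soft_tissue,20.0,0.070,8.0e-11
lung,20.0,0.070,8.0e-11
skeleton,1e-09,3.6,6e-13
skeleton,2.5e-08,1.26,1.2e-13
skeleton,1e-06,0.96,2e-14
skeleton,1e-04,0.72,7.5e-15
skeleton,0.01,0.57,3e-13
skeleton,0.1,0.36,3e-12
skeleton,1.0,0.15,1.3e-11
skeleton,5.0,0.069,2.8e-11
skeleton,10.0,0.054,3.4e-11
skeleton,20.0,0.042,4e-11
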