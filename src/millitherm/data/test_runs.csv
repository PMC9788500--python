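run_id,omega_rpm,omega_printed_rpm,bead_loading,bead_size_um,fit_qgen_J_min,fit_ua_J_min_C,fit_lpm_rmse_C,fit_ebm_rmse_C,pl_qgen_J_min,pl_ua_J_min_C,pl_lpm_rmse_C,pl_ebm_rmse_C,ml_qgen_J_min,ml_ua_J_min_C,ml_lpm_rmse_C,ml_ebm_rmse_C
28,2500,2500,0.45,400,1481,68,0.35,0.51,1634,78,0.74,0.93,1792,77,1.51,1.02
29,2500,2500,0.55,400,2495,101,0.42,0.59,2118,91,1.49,1.02,2506,95,1.44,1.00
30,3500,3500,0.45,400,4084,118,0.50,1.56,4519,137,1.56,2.22,4555,132,0.59,2.17
31,3500,2500,0.55,400,5567,147,0.56,1.01,5856,160,1.02,1.17,5911,162,1.19,1.29
32,4200,4000,0.35,100,3185,84,0.66,1.13,4180,129,4.13,4.17,4359,124,2.08,1.63
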