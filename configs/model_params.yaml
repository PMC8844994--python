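TVCL: 0.14
TVVc: 0.769
TVQ: 0.147
TVVp: 0.285
theta_PMA_CL_Hill: 7.02
theta_PMA_CL_Mat50: 197.0
theta_SCr_CL: 0.541
theta_WT_CL_Q: 0.75
theta_WT_V: 1.0
omega2_BSV_CL: 0.015015698014102928
omega2_BOV_CL: 0.017534370471081234
sigma_prop: 0.168
sigma_add: 1.76
WT_ref: 1.0
SCr_ref: 42.0
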