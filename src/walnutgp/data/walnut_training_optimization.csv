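trait_id,trait_group,pa_random_mean,pa_random_sd,pa_cdmean_mean,pa_cdmean_sd,pa_pevmean_mean,pa_pevmean_sd,pa_meanrel_mean,pa_meanrel_sd,gain_cdmean_printed,gain_pevmean_printed,gain_meanrel_printed
PHENO_d,phenology,0.49,0.15,0.44,0.06,0.45,0.08,0.47,0.00,-10,-8,-4
PHENO_bd,phenology,0.75,0.06,0.80,0.01,0.80,0.01,0.55,0.00,7,7,-27
PHENO_ffd,phenology,0.77,0.08,0.78,0.01,0.79,0.01,0.66,0.00,1,3,-14
PHENO_mfd,phenology,0.61,0.11,0.65,0.03,0.63,0.02,0.22,0.00,7,3,-64
NUT_l,nut,0.47,0.13,0.54,0.01,0.51,0.01,0.56,0.00,15,9,19
NUT_fd,nut,0.46,0.08,0.49,0.09,0.44,0.06,0.50,0.00,7,-4,9
NUT_pd,nut,0.50,0.09,0.46,0.04,0.39,0.05,0.30,0.00,-8,-22,-40
NUT_v,nut,0.46,0.20,0.46,0.01,0.39,0.07,0.43,0.00,0,-15,-7
NUT_esv,nut,0.46,0.11,0.52,0.02,0.43,0.05,0.50,0.00,13,-7,9
NUT_fr,nut,0.48,0.10,0.53,0.00,0.56,0.05,0.44,0.00,10,17,-8
NUT_w,nut,0.35,0.25,0.27,0.08,0.20,0.07,0.28,0.00,-23,-43,-0
SHELL_s,shell,0.23,0.16,0.26,0.02,0.29,0.01,0.47,0.00,13,26,104
SHELL_r,shell,0.30,0.17,0.25,0.02,0.29,0.01,0.47,0.00,-17,-3,57
SHELL_v,shell,0.23,0.20,0.15,0.07,0.12,0.09,0.27,0.00,-35,-48,17
SHELL_t,shell,0.11,0.12,0.20,0.10,0.21,0.15,0.17,0.00,82,91,55
SHELL_sa,shell,0.35,0.11,0.40,0.00,0.32,0.07,0.42,0.00,14,-9,20
SHELL_ss,shell,0.28,0.15,0.16,0.03,0.02,0.14,0.54,0.00,-43,-93,93
SHELL_fs,shell,0.14,0.10,0.08,0.03,0.09,0.10,0.24,0.00,-43,-36,71
QUAL_sfa,quality,0.45,0.11,0.46,0.02,0.47,0.04,0.37,0.00,2,4,-18
QUAL_mufa,quality,0.38,0.13,0.49,0.03,0.48,0.01,0.18,0.00,29,26,-53
QUAL_pufa,quality,0.38,0.09,0.33,0.01,0.35,0.03,0.13,0.00,-13,-8,-66
QUAL_t,quality,0.11,0.12,0.24,0.10,0.27,0.04,0.20,0.00,118,145,82
QUAL_vea,quality,0.02,0.09,0.12,0.11,0.21,0.03,0.02,0.00,500,950,0
KERNEL_v,kernel,0.49,0.14,0.46,0.05,0.41,0.04,0.43,0.00,-6,-16,-12
KERNEL_w,kernel,0.47,0.07,0.39,0.08,0.30,0.04,0.47,0.00,-17,-36,0
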