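trait_id,n_significant_snps,top_snp_pev,cum_top3_pev,mean_gp_accuracy,reported_method
PHENO_d,1,77.2,77.2,0.48,MAS/GS
PHENO_bd,5,30.6,64.7,0.74,MAS/GS
PHENO_ffd,2,36.2,67.4,0.76,MAS/GS
PHENO_mfd,2,6.1,8.0,0.59,GS
NUT_l,4,15.4,44.4,0.44,MAS/GS
NUT_fd,4,26.4,52.0,0.46,MAS/GS
NUT_pd,2,16.5,16.6,0.42,GS
NUT_v,6,17.33,50.8,0.45,MAS/GS
NUT_esv,4,17.1,50.1,0.44,MAS/GS
NUT_fr,4,20.4,42.6,0.43,MAS/GS
NUT_w,5,17.1,24.8,0.37,No method
SHELL_s,0,,,0.30,No method
SHELL_r,0,,,0.31,No method
SHELL_v,0,,,0.23,No method
SHELL_t,1,13.7,13.7,0.15,No method
SHELL_sa,2,16.5,32.6,0.36,MAS
SHELL_ss,2,14.8,27.0,0.22,No method
SHELL_fs,2,16.1,27.4,0.18,No method
QUAL_sfa,0,,,0.37,No method
QUAL_mufa,5,17.7,45.6,0.39,MAS
QUAL_pufa,0,,,0.34,No method
QUAL_t,8,18.2,44.8,0.08,MAS
QUAL_vea,2,13.8,19.1,-0.08,No method
KERNEL_v,3,25.0,65.5,0.49,MAS/GS
KERNEL_w,3,11.5,26.7,0.53,GS
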