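label,ctab_pct,size_nm,size_sd_nm,pdi,pdi_sd,zeta_mv,zeta_sd_mv
PE0,0,181,33,0.072,0.015,-6.92,0.8
PE2,2,136,12,0.153,0.040,36.9,8.4
PE4,4,168,23,0.090,0.021,12.8,1.5
PE5,6,174,29,0.171,0.027,49.5,5.2
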