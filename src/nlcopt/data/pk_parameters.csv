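drug,product,cmax_mg_per_l,tmax_h,auc_0_24_mg_h_per_l
STP,NLC,12.3,2.0,86.2
STP,commercial,16.7,2.0,89.2
CBD,NLC,1.27,1.0,8.0
CBD,commercial,0.61,0.5,5.4
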