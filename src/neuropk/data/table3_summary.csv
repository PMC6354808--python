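group,metric,median,q1,q3
all,cmax_plasma,177.8,169.7,236.4
all,auc_plasma,111.3,95.7,136.5
all,cmax_csf,6.8,5.2,9.4
all,tmax_csf,1.8,1,2
all,auc_csf,26.3,16.6,43.1
all,t_half,1.7,1.5,1.9
all,pen_cmax_pct,3,2,6
all,pen_auc_pct,20,18,45
csf_sampled,cmax_plasma,177.8,169.7,236.4
csf_sampled,auc_plasma,111.3,95.7,136.5
csf_sampled,cmax_csf,7.1,3.8,9.4
csf_sampled,tmax_csf,1.2,0.9,2
csf_sampled,auc_csf,21.9,13.7,43.1
csf_sampled,t_half,1.7,1.5,1.9
csf_sampled,pen_cmax_pct,3,2,6
csf_sampled,pen_auc_pct,19,12,45
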