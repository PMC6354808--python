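animal,cmax_plasma,auc_plasma,cmax_csf,tmax_csf,auc_csf,t_half,pen_cmax_pct,pen_auc_pct,csf_sampled
1,169.7,92.8,3.8,1.2,16.6,2.2,2,18,1
2,433.4,163.5,8.5,0.4,10.5,0.6,2,6,1
3,170,108.6,12,2,51.0,1.4,7,47,0
4,197.4,112.4,3.6,1,13.7,1.9,2,12,1
5,251.7,145.8,6.4,1.8,28.0,1.9,3,19,0
6,205.6,123.0,6.8,1.8,29.8,1.8,3,24,0
7,236.4,136.5,6,1.8,26.3,1.9,3,19,1
8,153.4,95.7,9.4,2,43.1,1.7,6,45,1
9,177.8,100.1,7.1,0.9,21.9,1.5,4,22,1
10,167.5,94.8,5.2,1.2,18.5,1.7,3,20,0
11,173.1,111.3,11.7,2,51.2,1.5,7,46,1
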