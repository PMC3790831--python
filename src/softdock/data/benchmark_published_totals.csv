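method,subset,cutoff,n_complexes,n_success,total_hits
aspdock,enzyme_inhibitor,10,35,24,742
srm,enzyme_inhibitor,10,35,25,2348
aspdock,other,10,64,26,831
srm,other,10,64,31,1094
aspdock,all,10,99,50,1573
srm,all,10,99,56,3442
aspdock,all,5,99,23,284
srm,all,5,99,31,834
srm_alpha2,all,10,99,53,3051
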