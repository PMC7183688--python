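snp_id,group,n_nn,n_nr,n_rr
rs2230926,control,1989,213,5
rs2230926,case,1069,240,9
rs131654,control,572,1116,519
rs131654,case,274,669,375
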