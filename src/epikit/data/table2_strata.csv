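snpA_level,snpB_level,controls,cases
N,nn,509,232
N,nr,999,540
N,rr,481,297
R,nn,63,42
R,nr,117,129
R,rr,38,78
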