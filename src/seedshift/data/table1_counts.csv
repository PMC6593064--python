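snp_id,genotype,case_n,control_n
rs1128334,GG,39,30
rs1128334,GA,18,9
rs1128334,AA,9,3
rs4937333,CC,21,15
rs4937333,CT,24,24
rs4937333,TT,21,3
rs1128355,GG,66,42
rs11554584,GG,66,42
rs12288765,TT,66,42
rs35034701,AA,66,42
rs57498864,AA,66,42
rs58920409,TT,66,42
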