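name	length	order_index
gatB	369	0
coxA	402	1
hcpA	444	2
ftsZ	435	3
fbpA	429	4
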