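mask	delta_isc
WT	0.00
a99	6.52
a100	2.08
a101	4.77
b98	3.24
b99	0.81
b100	1.39
alpha	9.63
beta	3.88
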