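name	x	y
AF3	-0.5314	1.2116
F7	-1.4625	0.8841
F3	-0.7198	0.7609
FC5	-1.2365	0.2986
T7	-1.6498	-0.3140
P7	-1.1199	-1.1356
O1	-0.3783	-1.4462
O2	0.3844	-1.4448
P8	1.1280	-1.1282
T8	1.6546	-0.2921
FC6	1.2427	0.3115
F4	0.7408	0.7760
F8	1.4612	0.8887
AF4	0.5509	1.1990
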