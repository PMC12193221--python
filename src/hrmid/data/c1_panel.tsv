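species	peaks	batch
H. ligurriens	76.53	run1
B. peregrina	76.77	run1
P. dux	75.97	run1
M. domestica	75.22	run1
P. scopariiformis	75.90	run1
S. princeps	74.75;77.65;80.32	run1
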