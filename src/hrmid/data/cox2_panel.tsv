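species	peaks	batch
C. megacephala	76.22	run1
H. ligurriens	76.70	run1
A. rufifacies	76.45	run1
B. peregrina	76.73	run1
P. dux	77.07	run1
P. misera	76.32	run1
P. sericea	77.20	run1
P. ruficornis	76.52	run1
S. princeps	76.88	run1
M. domestica	75.70	run1
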