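species	conc_ng_per_ul
C. megacephala	37.1
H. ligurriens	7.89
A. rufifacies	10.87
B. peregrina	12.57
P. dux	138
P. misera	73.87
P. sericea	103.67
P. ruficornis	3.83
S. princeps	51.6
M. domestica	232
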