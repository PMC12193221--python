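species	peaks	batch
B. peregrina	75.26	larva_run
P. dux	77.40	larva_run
S. princeps	77.20	larva_run
P. misera	76.96	larva_run
P. sericea	77.14	larva_run
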