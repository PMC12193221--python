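species	peaks	batch
B. peregrina	76.83	run2
P. dux	77.17	run2
P. misera	76.35	run2
P. sericea	77.22	run2
P. ruficornis	76.60	run2
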