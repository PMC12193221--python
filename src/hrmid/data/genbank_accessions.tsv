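species	coxi	coxii
C. megacephala	NC_019633.1:1428-2961	NC_019633.1:3033-3720
A. rufifacies	NC_019634.1:1415-2948	NC_019634.1:3020-3707
H. ligurriens	NC_019638.1:1417-2950	NC_019638.1:3022-3709
P. dux	NC_039826.1:1411-2944	NC_039826.1:3018-3705
P. misera	NC_036107.1:1415-2945	NC_036107.1:3018-3708
P. peregrina	NC_023532.1:1413-2946	NC_023532.1:3018-3705
S. princeps	NC_042759.1:1434-2967	NC_042759.1:3041-3728
M. domestica	NC_024855.1:1410-2943	NC_024855.1:3014-3698
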