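pair	fwd	rev	target_bp	gene	anneal_c	source	selected
C1-J-2495/C1-N-2800	CAGCTACTTTATGAGCTTTAGG	CATTTCAAGCTGTGTAAGCATC	278	COXI	48	literature	yes
16SrF/16SrR	CGCTGTTATCCCTAAGGTAA	CTGGTATGAAAGGTTTGACG	289	16S		literature	no
COI-1502/COI-1758	AGCGGGAATAGTGGGAA	ATGTTAGAGCAGGAGGT	257	COXI		designed	no
COI-269/COI-378	CCCCTGCACTAACTTTAC	TGATGCTCCACCATGT	110	COXI		designed	no
COI-1499/COI-1757	TTGAGCGGGAATAGTGG	TGTTAGAGCAGGAGGTA	259	COXI		designed	no
COI-359/COI-624	ATTGCCCATGGAGGT	CCTGCAGGGTCAAAAA	266	COXI		designed	no
COI-59/COI-317	TCGGAGCATGATCTGGTAT	GCAGGAGGTAATAATCAAAA	259	COXI		designed	no
COI-2600/COI-2783	TGTTCATTGATTCCCTCT	AGAAATTACATTTCAAGCTGTGTAA	184	COXI		designed	no
COI-118/COI-392	GGTCATCCAGGAGCACTAA	GATAACGGAGGGTAAACAG	275	COXI		designed	no
COI-794/COI-1286	CATTTGGTTCATTAGGGATA	AAGAAGTGTTGAGGGAAGA	493	COXI		designed	no
COX2-229/COX2-479	GCTTTCCCTTCTTTACGAT	ATTACATCAGCAGCGGTTA	252	COXII		designed	no
COX2-224/COX2-521	TTATTGCTTTTCCTTCACT	CCATCAACCTTTACTCCTA	298	COXII		designed	no
COX2-365/COX2-521	TTATTGCTTTTCCTTCACT	CCATCAACCTTTACTCCTA	157	COXII		designed	no
COX2-519/COX2-615	TGGAACCCCTGGACGACTTA	ACTGTGATTAGCTCCGCAAA	97	COXII	53	designed	yes
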