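domain	kind	pattern	required
D1-D1'	helix	stem=6..8;loop=3..6;window=40	yes
D2	motif	ACCTCCAAAGCAACA	yes
spacer_D2_D3	spacer	-	yes
D3	motif	GGTAY	yes
tRNA-Ile	motif	AACCCACGATCACCAACACCCATAA	no
V2	helix	stem=5..6;loop=3..5;window=30	no
tRNA-Ala	motif	CACAATGGCACAACCTACACAAC	no
BoxB	helix	stem=6..7;loop=4..6;window=30	yes
BoxA	motif	ACAAAATCTGCAA	yes
D4	motif	CACTACAACTCA	yes
V3	helix	stem=5..6;loop=3..5;window=30	yes
D5	motif	CCTACA	yes
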