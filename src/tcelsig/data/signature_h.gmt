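signature-H	15 T-cell-restricted genes selected by the six-round procedure	CD2	CD247	CD28	CD3D	CD3G	CD6	GPR171	GZMK	ICOS	ITK	KLRB1	PYHIN1	TIGIT	TRAT1	TRBC1
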