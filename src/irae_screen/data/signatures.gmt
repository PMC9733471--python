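CytolyticIndex	geometric mean of granzyme A and perforin expression	GZMA	PRF1
IFNgammaSignature	six-gene interferon-gamma signature	IFNG	STAT1	IDO1	CXCL9	CXCL10	HLA-DRA
ExpandedImmuneSignature	eighteen-gene expanded immune signature	CD3D	IDO1	CIITA	CD3E	CCL5	GZMK	CD2	HLA-DRA	CXCL13	IL2RG	NKG7	HLA-E	CXCR6	LAG3	TAGAP	CXCL10	STAT1	GZMB
CD8TExhaustion	CD8+ T-cell exhaustion transcriptional signature	LAG3	PDCD1	HAVCR2	TIGIT	CTLA4
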