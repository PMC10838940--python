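CAF_markers	classic cancer-associated fibroblast markers	PDGFRA	PDGFRB	PDPN	FAP	THY1	COL1A1	COL1A2	COL3A1	ACTA2	S100A4
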