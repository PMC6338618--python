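BCLM_UP	lung-metastasis signature genes repressed by reversal hits	ANGPTL4	MMP1	PTGS2	TNC
BCLM_DN	lung-metastasis signature genes induced by reversal hits	LY6E	RARRES3
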