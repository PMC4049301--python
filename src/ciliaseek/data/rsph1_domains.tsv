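protein_id	start	end	label	source
RSPH1	26	43	MORN	Pfam
RSPH1	44	66	MORN	Pfam
RSPH1	67	89	MORN	Pfam
RSPH1	90	112	MORN	Pfam
RSPH1	113	133	MORN	Pfam
RSPH1	137	152	MORN	Pfam
RSPH1	159	181	MORN	Pfam
RSPH1	238	251	low_complexity	SMART
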