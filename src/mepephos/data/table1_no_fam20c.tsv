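peptide	start	end	phospho	counts	expect	ppm	conservation
RINQELSSKENIVQER	36	51	43	1			21
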