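# MALDI peak list (linear mode, average MH+), ASARM-containing tryptic
# peptide of the K509A/K515A construct coexpressed with the kinase.
# Only the two printed m/z values are transcribed.
# m/z
4840.4
5640.8
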