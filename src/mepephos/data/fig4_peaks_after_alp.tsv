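# MALDI peak list after alkaline-phosphatase dephosphorylation of the
# same fraction: the ladder collapses to the unmodified peptide.
# m/z
4842.1
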