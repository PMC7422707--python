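{
  "comment": "Recombinant MEPE C-terminal construct. The base chain is the printed mature-numbering span 489-508 (the ASARM-containing tail; the full 508-residue sequence is not packaged). Tags follow the base immediately; the two tail lysines K509/K515 (mature numbering continued into the tags) are mutated to alanine in the mutant form so trypsin leaves one long C-terminal peptide.",
  "base": {
    "id": "MEPE_tail",
    "residues": "RRDDSSESSDSGSSSESDGD",
    "numbering_offset": 489
  },
  "tags": [
    ["linker_KLGP", "KLGP"],
    ["myc", "EQKLISEEDL"],
    ["linker_NSAVD", "NSAVD"],
    ["his6", "HHHHHH"]
  ],
  "mutations_wt": [],
  "mutations_mutant": ["K509A", "K515A"],
  "asarm_region": {"name": "ASARM_tail", "start": 489, "end": 508}
}
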