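{
  "name": "lrp8",
  "description": "Eight residues that discriminate globally-acting Lrp orthologs (Enterobacteriales + Vibrionales) from locally-acting ones (Pasteurellales). Positions are 1-based residue numbers on the anchor sequence (E. coli Lrp), which carries the full N-terminal tail so its residue numbering coincides with the master-alignment numbering.",
  "anchor_id": "NP_415409.1",
  "coordinate": "anchor",
  "positions": [14, 21, 36, 40, 60, 80, 128, 136],
  "global_consensus": [["D"], ["N"], ["E"], ["R"], ["F"], ["F"], ["S"], ["D", "E"]],
  "local_consensus": [["A"], ["K"], ["D"], ["K"], ["V"], ["V"], ["A"], ["T"]]
}
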