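# C. elegans neuronal set. Primary IDs are the systematic worm gene names the
# expression matrices carry; transporter/enzyme family names kept as aliases.
species: Caenorhabditis elegans
classes:
  Aminergic:
    - "cat-1 (Vmat)"
    - "tph-1 (Tph)"
    - "bas-1 (Ddc)"
    - "mod-5 (SerT)"
    - "cat-2 (Th)"
    - "dat-1 (Dat)"
    - "tdc-1 (Tdc)"
    - "tbh-1 (Tbh)"
  Cholinergic:
    - "cha-1 (Chat)"
    - "unc-17 (VAChT)"
    - "cho-1 (ChT)"
  GABAergic:
    - "unc-25 (Gad)"
    - "unc-47 (VGAT)"
    - "snf-11 (GAT)"
  Glutamatergic:
    - "eat-4 (Vglut)"
provenance:
  Aminergic: "serotonergic (tph-1), dopaminergic (cat-2) and tyraminergic/octopaminergic (tdc-1, tbh-1) subtypes grouped into a single monoaminergic category"
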