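# Danio rerio (zebrafish) brain, 23-25 dpf. The neuron-selection gating rule
# is recorded with OR semantics: selecting cells positive for ANY of the nine
# neurotransmitter markers is the reading under which the selected set equals
# the union of the classified classes; this is an interpretation, recorded
# here rather than hard-coded.
species: Danio rerio
classes:
  Cholinergic:
    - "slc18a3a (VAChT)"
    - "slc44a2 (ChT2)"
    - "slc44a5a (ChTl5a)"
    - "slc44a5b (ChTl5b)"
  GABAergic:
    - "gad1b"
    - "gad2"
    - "slc32a1 (VGAT)"
  Glutamatergic:
    - "slc17a6b (VGlut2.1)"
  Glycinergic:
    - "slc6a9 (GLYT1)"
gating: "gad1b > 1 or gad2 > 1 or slc32a1 > 1 or slc17a6b > 1 or slc18a3a > 1 or slc44a2 > 1 or slc44a5b > 1 or slc44a5a > 1 or slc6a9 > 1"
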