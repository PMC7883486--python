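# Mus musculus adult brain (young and aging atlases share this panel).
species: Mus musculus
classes:
  GABAergic:
    - "Gad1"
    - "Gad2"
  Glutamatergic:
    - "Slc17a7 (VGlut1)"
    - "Slc17a6 (VGlut2)"
    - "Slc17a8 (VGlut3)"
  Cholinergic:
    - "Slc18a3 (VAChT)"
    - "Gm5741"
    - "Slc5a7 (Cht1)"
    - "Glyt2"
  Aminergic:
    - "Slc18a2 (Vmat2)"
    - "Th"
provenance:
  Cholinergic: >-
    Glyt2 (glycine transporter 2) is recorded inside the cholinergic class as
    listed in the source marker description; whether it was meant to define a
    separate glycinergic class is ambiguous there, so it is kept as written.
  Aminergic: "Vmat2 and Th expression do not perfectly overlap; either marks the class"
# Neuron selection reads most naturally as a union over the synaptic and
# neurotransmitter markers (an all-AND reading would keep only cells positive
# for every marker at once); recorded as OR — an interpretation, like the
# zebrafish rule.
gating: "Syt1 > 1 or Slc17a7 > 1 or Slc17a6 > 1 or Slc17a8 > 1 or Gad1 > 1 or Gad2 > 1 or Slc18a3 > 1 or Gm5741 > 1 or Slc5a7 > 1 or Slc18a2 > 1 or Th > 1"
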