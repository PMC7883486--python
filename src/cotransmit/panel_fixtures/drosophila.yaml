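# D. melanogaster brain (larval and adult atlases use the same symbols).
species: Drosophila melanogaster
classes:
  Cholinergic: ["VAChT"]
  Glutamatergic: ["VGlut"]
  GABAergic: ["Gad1"]
  Aminergic: ["Vmat"]
gating: "nSyb > 1 and elav > 1 and Syt1 > 1"
provenance:
  GABAergic: "glutamic acid decarboxylase 1"
  Cholinergic: "vesicular acetylcholine transporter"
  Glutamatergic: "vesicular glutamate transporter"
  Aminergic: "vesicular monoamine transporter"
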