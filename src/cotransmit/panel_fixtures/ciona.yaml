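# Ciona intestinalis larval brain.
species: Ciona intestinalis
classes:
  GABAergic: ["GAD1/2", "VGAT"]
  Cholinergic: ["VAChT", "CHAT"]
  Glutamatergic: ["VGlut"]
provenance:
  GABAergic: "glutamate decarboxylase 1/2 and vesicular GABA transporter"
  Cholinergic: "vesicular acetylcholine transporter and acetylcholine transporter"
  Glutamatergic: "vesicular glutamate transporter"
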