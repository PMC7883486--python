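# Hydra vulgaris nerve net: two classes distinguishable in the current
# genome annotation.
species: Hydra vulgaris
classes:
  GABAergic: ["PNPO"]
  Cholinergic: ["ChT"]
provenance:
  GABAergic: "pyridoxine-5'-phosphate oxidase, cofactor producer for glutamate->GABA conversion"
  Cholinergic: "choline transporter, choline uptake into acetylcholine-synthesizing neurons"
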