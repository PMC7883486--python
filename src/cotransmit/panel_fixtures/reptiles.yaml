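# Reptile dorsal telencephalon (lizard Pogona vitticeps and turtle Trachemys
# scripta use the same two-class panel). "SCL17A7" is recorded verbatim from
# the source marker list; "SLC17A7" (the standard VGlut1 symbol) is kept as
# an alias so either spelling in a matrix resolves.
species: reptiles
classes:
  Glutamatergic: ["SCL17A7 (SLC17A7, VGlut1)"]
  GABAergic: ["GAD2"]
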