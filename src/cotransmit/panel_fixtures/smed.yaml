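# Schmidtea mediterranea brain. Primary IDs are the dd_Smed_v4 transcriptome
# contigs used by the atlas; family names kept as aliases.
species: Schmidtea mediterranea
classes:
  Aminergic:
    - "dd_Smed_v4_19744_0_1 (Vmat)"
    - "dd_Smed_v4_12700_0_1 (SerT)"
    - "dd_Smed_v4_21108_0_1 (Ddc)"
    - "dd_Smed_v4_8392_0_1 (Tph)"
    - "dd_Smed_v4_16581_0_1 (Th)"
  Cholinergic:
    - "dd_Smed_v4_11968_0_1 (Chat)"
    - "dd_Smed_v4_6208_0_1 (Chat2)"
  GABAergic:
    - "dd_Smed_v4_12653_0_1 (Gad)"
    - "dd_Smed_v4_6616_0_19 (TauT)"
    - "dd_Smed_v4_11826_0_1 (GAT)"
  Glutamatergic:
    - "dd_Smed_v4_10192_0_1 (Vglut)"
  Glycinergic:
    - "dd_Smed_v4_5713_0_1 (GlyT)"
gating: "dd_Smed_v4_4222_0_1 > 1"
provenance:
  Aminergic: "vesicular monoamine transporter, serotonin transporter, dopa decarboxylase, tryptophan/tyrosine hydroxylases"
  Cholinergic: "two choline acetyltransferase contigs"
  GABAergic: "glutamic acid decarboxylase, taurine transporter, GABA transporter"
  Glutamatergic: "vesicular glutamate transporter"
  Glycinergic: "glycine transporter"
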