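category	top_genes
cellular_cycle_and_signaling	EDN1,AKT1,IL1B,INS
membrane_and_transport	CDK5,ATP1B1
metabolic_immunological_other	PTK2B,MTOR,APP,KIT,LEP,MAPK3,SRC
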