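category	go_id	term
cellular_cycle_and_signaling	GO:0045595	Regulation of cell differentiation
cellular_cycle_and_signaling	GO:0007267	Cell-cell signaling
cellular_cycle_and_signaling	GO:0042592	Homeostatic process
cellular_cycle_and_signaling	GO:0048585	Negative regulation of response to stimulus
cellular_cycle_and_signaling	GO:0007049	Cell cycle
cellular_cycle_and_signaling	GO:0033043	Regulation of organelle organization
cellular_cycle_and_signaling	GO:0051240	Positive regulation of multicellular organismal process
cellular_cycle_and_signaling	GO:0023056	Positive regulation of signaling
cellular_cycle_and_signaling	GO:0098772	Molecular function regulator
membrane_and_transport	GO:0005215	Transporter activity
membrane_and_transport	GO:0006811	Ion transport
membrane_and_transport	GO:0051049	Regulation of transport
membrane_and_transport	GO:0040011	Locomotion
membrane_and_transport	GO:0055085	Transmembrane transport
membrane_and_transport	GO:0070727	Cellular macromolecule localization
membrane_and_transport	GO:0046907	Intracellular transport
membrane_and_transport	GO:0022610	Biological adhesion
metabolic_immunological_other	GO:0044281	Small molecule metabolic process
metabolic_immunological_other	GO:0006629	Lipid metabolic process
metabolic_immunological_other	GO:0031399	Regulation of protein modification process
metabolic_immunological_other	GO:0051174	Regulation of phosphorus metabolic process
metabolic_immunological_other	GO:0019219	Regulation of nucleobase containing compound metabolic process
metabolic_immunological_other	GO:0002520	Immune system development
metabolic_immunological_other	GO:0022008	Neurogenesis
metabolic_immunological_other	GO:0000003	Reproduction
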