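source_name	canonical_name
B cells naive	B_naive
B cells memory	B_memory
Plasma cells	Plasma
T cells CD8	CD8T
T cells CD4 naive	CD4_naive
T cells CD4 memory resting	CD4_memory_resting
T cells CD4 memory activated	CD4_memory_activated
T cells follicular helper	Tfh
T cells regulatory (Tregs)	Treg
T cells gamma delta	Tgd
NK cells resting	NK_resting
NK cells activated	NK_activated
Monocytes	Monocytes
Macrophages M0	M0
Macrophages M1	M1
Macrophages M2	M2
Dendritic cells resting	DC_resting
Dendritic cells activated	DC_activated
Mast cells resting	Mast_resting
Mast cells activated	Mast_activated
Eosinophils	Eosinophils
Neutrophils	Neutrophils
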