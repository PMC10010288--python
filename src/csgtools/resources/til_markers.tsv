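cell_type	gene
cd8_t_cells	CD8A
cd8_t_cells	CD8B
t_cells	CD3D
t_cells	CD3E
t_cells	CD3G
t_cells	CD6
b_cells	MS4A1
b_cells	CD19
nk_cells	NKG7
nk_cells	GNLY
macrophages	CD68
macrophages	CD163
cytotoxic_cells	PRF1
cytotoxic_cells	GZMA
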