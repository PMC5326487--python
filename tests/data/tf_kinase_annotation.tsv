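gene_id	class	family
AT1G21700	TF	MYB-related
AT2G37590	TF	C2C2-Dof
AT5G14340	TF	MYB
AT4G32800	TF	AP2-EREBP
AT1G17460	TF	MYB-related
AT1G77800	TF	PHD
AT4G34220	kinase	LRR-kinase
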