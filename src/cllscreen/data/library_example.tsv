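entry_id	kind	component_1	component_2	min_nM	max_nM	n_points
venetoclax	single	venetoclax		1	10000	5
BGB-11417	single	BGB-11417		1	10000	5
idelalisib	single	idelalisib		1	10000	5
ibrutinib	single	ibrutinib		1	10000	5
bortezomib	single	bortezomib		1	10000	5
ixazomib_citrate	single	ixazomib citrate		1	10000	5
cobimetinib	single	cobimetinib		1	10000	5
copanlisib	single	copanlisib		0.1	1000	5
dasatinib	single	dasatinib		0.1	1000	5
idelalisib+venetoclax	combination	idelalisib	venetoclax	1	10000	5
copanlisib+BGB-11417	combination	copanlisib	BGB-11417	0.1	1000	5
cobimetinib+venetoclax	combination	cobimetinib	venetoclax	1	10000	5
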