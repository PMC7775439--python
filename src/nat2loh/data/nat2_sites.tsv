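rsid	chrom	pos	cds_pos	ref	alt	role
rs1801279	chr8	18400194	191	G	A	classifying
rs1041983	chr8	18400285	282	C	T	classifying
rs1801280	chr8	18400344	341	T	C	classifying
rs1799929	chr8	18400484	481	C	T	classifying
rs1799930	chr8	18400593	590	G	A	classifying
rs1208	chr8	18400806	803	A	G	classifying
rs1799931	chr8	18400860	857	G	A	classifying
rs144176822	chr8	18400582	579	G	T	auxiliary
rs2552	chr8	18399825	0	A	G	auxiliary
rs4646247	chr8	18399948	0	C	T	auxiliary
rs971473	chr8	18401050	0	G	A	auxiliary
rs45547533	chr8	18401188	0	C	T	auxiliary
rs721398	chr8	18401402	0	G	A	auxiliary
rs721399	chr8	18401530	0	T	C	auxiliary
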