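name	group	phenotype	apa_sensitive	pattern
*4	*4	rapid	False	
*5A	*5	slow	True	rs1801280:C;rs1799929:T
*5B	*5	slow	True	rs1801280:C;rs1799929:T;rs1208:G
*5C	*5	slow	True	rs1801280:C;rs1208:G
*5D	*5	slow	True	rs1801280:C
*6A	*6	slow	True	rs1041983:T;rs1799930:A
*7B	*7	slow	False	rs1041983:T;rs1799931:A
*12A	*12	rapid	False	rs1208:G
*14A	*14	slow	True	rs1801279:A
*14B	*14	slow	True	rs1801279:A;rs1041983:T
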