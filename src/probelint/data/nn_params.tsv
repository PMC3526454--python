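# Unified DNA nearest-neighbor parameters (1 M NaCl reference state).
# kind=stack: key is the 5'->3' top-strand dinucleotide of a Watson-Crick
#   stack; dh in kcal/mol, ds in cal/(mol*K).
# kind=hairpin_loop / internal_loop / bulge_loop: key is the number of
#   unpaired loop bases; dg37 in kcal/mol (treated as entropic when scaled
#   to other temperatures).
kind	key	dh	ds	dg37
stack	AA	-7.9	-22.2
stack	TT	-7.9	-22.2
stack	AT	-7.2	-20.4
stack	TA	-7.2	-21.3
stack	CA	-8.5	-22.7
stack	TG	-8.5	-22.7
stack	GT	-8.4	-22.4
stack	AC	-8.4	-22.4
stack	CT	-7.8	-21.0
stack	AG	-7.8	-21.0
stack	GA	-8.2	-22.2
stack	TC	-8.2	-22.2
stack	CG	-10.6	-27.2
stack	GC	-9.8	-24.4
stack	GG	-8.0	-19.9
stack	CC	-8.0	-19.9
hairpin_loop	3			3.5
hairpin_loop	4			3.5
hairpin_loop	5			3.3
hairpin_loop	6			4.0
hairpin_loop	7			4.2
hairpin_loop	8			4.3
hairpin_loop	9			4.5
hairpin_loop	10			4.6
hairpin_loop	11			4.8
hairpin_loop	12			5.0
hairpin_loop	13			5.1
hairpin_loop	14			5.1
hairpin_loop	15			5.2
hairpin_loop	16			5.3
hairpin_loop	17			5.4
hairpin_loop	18			5.5
hairpin_loop	19			5.6
hairpin_loop	20			5.7
hairpin_loop	21			5.8
hairpin_loop	22			5.8
hairpin_loop	23			5.9
hairpin_loop	24			6.0
hairpin_loop	25			6.1
hairpin_loop	26			6.1
hairpin_loop	27			6.2
hairpin_loop	28			6.2
hairpin_loop	29			6.3
hairpin_loop	30			6.3
internal_loop	3			3.2
internal_loop	4			3.6
internal_loop	5			4.0
internal_loop	6			4.4
internal_loop	7			4.6
internal_loop	8			4.8
internal_loop	9			4.9
internal_loop	10			4.9
internal_loop	11			5.1
internal_loop	12			5.2
internal_loop	13			5.3
internal_loop	14			5.4
internal_loop	15			5.5
internal_loop	16			5.6
internal_loop	17			5.7
internal_loop	18			5.8
internal_loop	19			5.9
internal_loop	20			5.9
internal_loop	21			6.0
internal_loop	22			6.1
internal_loop	23			6.1
internal_loop	24			6.2
internal_loop	25			6.3
internal_loop	26			6.3
internal_loop	27			6.4
internal_loop	28			6.5
internal_loop	29			6.5
internal_loop	30			6.6
bulge_loop	1			4.0
bulge_loop	2			2.9
bulge_loop	3			3.1
bulge_loop	4			3.2
bulge_loop	5			3.3
bulge_loop	6			3.5
bulge_loop	7			3.7
bulge_loop	8			3.9
bulge_loop	9			4.1
bulge_loop	10			4.3
bulge_loop	11			4.4
bulge_loop	12			4.5
bulge_loop	13			4.6
bulge_loop	14			4.8
bulge_loop	15			4.9
bulge_loop	16			5.0
bulge_loop	17			5.1
bulge_loop	18			5.2
bulge_loop	19			5.3
bulge_loop	20			5.3
bulge_loop	21			5.4
bulge_loop	22			5.4
bulge_loop	23			5.5
bulge_loop	24			5.5
bulge_loop	25			5.6
bulge_loop	26			5.7
bulge_loop	27			5.7
bulge_loop	28			5.8
bulge_loop	29			5.8
bulge_loop	30			5.9
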