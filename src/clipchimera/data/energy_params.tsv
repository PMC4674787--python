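kind	key	value
# Approximate Turner-style nearest-neighbour stacks, kcal/mol at 37C.
# stack key = pair1|pair2 (each pair = miRNA base + target base, RNA letters),
# helix read 5'->3' along the miRNA. Missing entries are completed by the
# strand-swap symmetry stack[p|q] = stack[rev(q)|rev(p)]; doubly specified
# entries are averaged so the table is exactly symmetric.
stack	AU|AU	-0.93
stack	AU|UA	-1.10
stack	UA|AU	-1.33
stack	CG|UA	-2.08
stack	CG|AU	-2.11
stack	GC|UA	-2.24
stack	GC|AU	-2.35
stack	CG|GC	-2.36
stack	GC|GC	-3.26
stack	GC|CG	-3.42
stack	AU|GU	-0.80
stack	AU|UG	-1.00
stack	UA|GU	-1.00
stack	UA|UG	-1.30
stack	CG|GU	-2.00
stack	CG|UG	-1.50
stack	GC|GU	-1.50
stack	GC|UG	-1.90
stack	GU|GU	-0.50
stack	UG|UG	-0.50
stack	GU|UG	-0.20
stack	UG|GU	-0.30
# bulge loop cost by number of unpaired bases (one strand)
bulge	1	3.8
bulge	2	2.8
bulge	3	3.2
bulge	4	3.6
bulge	5	4.0
bulge	6	4.4
bulge	7	4.6
bulge	8	4.8
bulge	9	4.9
bulge	10	5.0
bulge	11	5.1
bulge	12	5.2
bulge	13	5.3
bulge	14	5.4
bulge	15	5.5
# interior loop cost by total unpaired bases (both strands)
interior	2	2.0
interior	3	2.4
interior	4	2.8
interior	5	3.1
interior	6	3.4
interior	7	3.7
interior	8	4.0
interior	9	4.2
interior	10	4.4
interior	11	4.6
interior	12	4.8
interior	13	5.0
interior	14	5.2
interior	15	5.3
interior	16	5.4
interior	17	5.5
interior	18	5.6
interior	19	5.7
interior	20	5.8
interior	21	5.9
interior	22	6.0
interior	23	6.1
interior	24	6.2
interior	25	6.3
interior	26	6.4
interior	27	6.5
interior	28	6.6
interior	29	6.7
interior	30	6.8
# terminal penalty per duplex end, by closing pair
terminal	AU	0.45
terminal	UA	0.45
terminal	GC	0.00
terminal	CG	0.00
terminal	GU	0.45
terminal	UG	0.45
# hard cap on bulge/interior run length per strand
limit	max_loop	15
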