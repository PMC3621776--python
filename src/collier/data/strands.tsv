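# V-domain beta strands of the framework regions, in sequence order.
# Columns: strand name, first IMGT position, last IMGT position,
# one-layer column index, sheet ("front" | "back") in the two-layer view,
# two-layer column index within that sheet.
# The per-strand delimitations tile the four FR-IMGT regions and are an
# approximation of the standard Collier de Perles layout; the two-layer
# sheet split is [A,B,E,D] / [G,F,C,C',C''].
A	1	15	0	front	0
B	16	26	1	front	1
C	39	46	2	back	2
C'	47	55	3	back	3
C''	66	74	4	back	4
D	75	84	5	front	3
E	85	96	6	front	2
F	97	104	7	back	1
G	118	128	8	back	0
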