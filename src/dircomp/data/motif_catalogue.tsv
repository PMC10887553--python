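# Default directed-motif catalogue, version 1.
# One class per line: id, node count, row-major adjacency bits of the
# canonical (lexicographically minimal) labeling.
# Sizes 2 and 3 are the complete weakly connected enumerations.
# The 20 four-node classes are the sparsest canonical classes, ordered
# by edge count then code.
m1	2	0010
m2	2	0110
m3	3	000000110
m4	3	000001100
m5	3	000100100
m6	3	000001110
m7	3	000100110
m8	3	001001010
m9	3	001100010
m10	3	000101110
m11	3	001001110
m12	3	001100110
m13	3	001101100
m14	3	001101110
m15	3	011101110
m16	4	0000000000001110
m17	4	0000000000011100
m18	4	0000000001001010
m19	4	0000000001001100
m20	4	0000000100011000
m21	4	0000000101001000
m22	4	0000000110001000
m23	4	0000100010001000
m24	4	0000000000011110
m25	4	0000000001001110
m26	4	0000000001011010
m27	4	0000000001011100
m28	4	0000000011001100
m29	4	0000000100011010
m30	4	0000000101001010
m31	4	0000000101001100
m32	4	0000000101011000
m33	4	0000000110000110
m34	4	0000000110001010
m35	4	0000000110001100
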