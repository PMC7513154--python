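# Four-node toy structure with arcs A->B, B->C, B->D
node	A	2
node	B	2
node	C	2
node	D	2
arc	A	B
arc	B	C
arc	B	D
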