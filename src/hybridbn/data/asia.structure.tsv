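# Asia: 8-node chest-clinic diagnostic network (8 arcs, all binary)
node	asia	2
node	tub	2
node	smoke	2
node	lung	2
node	bronc	2
node	either	2
node	xray	2
node	dysp	2
arc	asia	tub
arc	smoke	lung
arc	smoke	bronc
arc	tub	either
arc	lung	either
arc	either	xray
arc	either	dysp
arc	bronc	dysp
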