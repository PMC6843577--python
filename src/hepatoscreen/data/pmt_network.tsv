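he shou wu	emodin
he shou wu	chrysophanol
he shou wu	chrysarobin
he shou wu	rhein
he shou wu	danthron
he shou wu	polygonumnolide c2
he shou wu	emodin dianthrone
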