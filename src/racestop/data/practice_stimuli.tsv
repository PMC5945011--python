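picture	category	onset	related_distractor	unrelated_distractor
hoed	headwear	h	pet	boot
schip	watercraft	sch	boot	pruim
peer	fruit	p	pruim	bijl
zaag	tool	z	bijl	pet
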