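picture	category	onset	related_distractor	unrelated_distractor
been	body part	b	arm	tafel
stoel	furniture	st	tafel	kat
hond	pet	h	kat	broek
jas	clothing	j	broek	koek
brood	baked goods	br	koek	vork
mes	cutlery	m	vork	bus
fiets	vehicle	f	bus	tulp
roos	flower	r	tulp	melk
kaas	dairy	k	melk	laars
schoen	footwear	sch	laars	krijt
pen	writing tool	p	krijt	zwaan
duif	bird	d	zwaan	haai
vis	fish	v	haai	sjaal
trui	knitwear	tr	sjaal	kop
glas	drinkware	gl	kop	maan
zon	celestial body	z	maan	mist
wolk	weather	w	mist	oor
neus	face part	n	oor	koord
touw	cordage	t	koord	pad
slang	reptile	sl	pad	troon
kroon	regalia	kr	troon	trom
fluit	instrument	fl	trom	speer
zwaard	weapon	zw	speer	mos
gras	ground cover	gr	mos	pols
knie	joint	kn	pols	trol
draak	mythical beast	dr	trol	struik
plant	houseplant	pl	struik	geest
spook	apparition	sp	geest	bel
klok	bell	kl	bel	duin
strand	coast	str	duin	graaf
prins	royalty	pr	graaf	tak
blad	foliage	bl	tak	boer
smid	trade	sm	boer	baard
snor	facial hair	sn	baard	vaan
vlag	banner	vl	vaan	elf
dwerg	fairy tale figure	dw	elf	krab
kwal	sea creature	kw	krab	koe
geit	farm animal	g	koe	beer
leeuw	wild animal	l	beer	prei
ui	vegetable	ui	prei	arm
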