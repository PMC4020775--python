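# alias	canonical
# Case-insensitive aliases; whitespace and underscores are stripped before
# lookup, so write aliases without spaces.
cox1	COI
cox2	COII
cox3	COIII
coxI	COI
coxII	COII
coxIII	COIII
co1	COI
co2	COII
co3	COIII
coi	COI
coii	COII
coiii	COIII
cytochromecoxidasesubunit1	COI
cytochromecoxidasesubunit2	COII
cytochromecoxidasesubunit3	COIII
cytochromecoxidasesubunitI	COI
cytochromecoxidasesubunitII	COII
cytochromecoxidasesubunitIII	COIII
nad1	ND1
nad2	ND2
nad3	ND3
nad4	ND4
nad4l	ND4L
nad5	ND5
nad6	ND6
nadh1	ND1
nadh2	ND2
nadh3	ND3
nadh4	ND4
nadh4l	ND4L
nadh5	ND5
nadh6	ND6
nd4l	ND4L
atp6	ATP6
atp8	ATP8
atpase6	ATP6
atpase8	ATP8
atpsynthasef0subunit6	ATP6
atpsynthasef0subunit8	ATP8
cytb	Cytb
cob	Cytb
cytochromeb	Cytb
rrnl	lrRNA
rrns	srRNA
l-rrna	lrRNA
s-rrna	srRNA
16srrna	lrRNA
12srrna	srRNA
16sribosomalrna	lrRNA
12sribosomalrna	srRNA
largesubunitribosomalrna	lrRNA
smallsubunitribosomalrna	srRNA
trna-ala	trnA
trna-arg	trnR
trna-asn	trnN
trna-asp	trnD
trna-cys	trnC
trna-gln	trnQ
trna-glu	trnE
trna-gly	trnG
trna-his	trnH
trna-ile	trnI
trna-lys	trnK
trna-met	trnM
trna-phe	trnF
trna-pro	trnP
trna-thr	trnT
trna-trp	trnW
trna-tyr	trnY
trna-val	trnV
trna-leu(cun)	trnL1
trna-leu(uur)	trnL2
trna-leu(taa)	trnL2
trna-leu(tag)	trnL1
trna-ser(agn)	trnS1
trna-ser(ucn)	trnS2
trna-ser(gct)	trnS1
trna-ser(tga)	trnS2
trnl1(tag)	trnL1
trnl2(taa)	trnL2
trns1(gct)	trnS1
trns2(tga)	trnS2
trnlcun	trnL1
trnluur	trnL2
trnsagn	trnS1
trnsucn	trnS2
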