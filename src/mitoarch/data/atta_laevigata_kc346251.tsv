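#mitoarch feature table
# Published annotation of the Atta laevigata mitochondrial genome
# (GenBank KC346251, 18,729 bp; the AT-rich control region after srRNA is
# only partially sequenced).  Coordinates are 1-based inclusive on the J
# strand; strand N marks minority-strand genes.
#genome_id=Atta_laevigata_KC346251
#length=18729
#circular=true
gene	gene_class	strand	start	end	start_codon	stop_codon
trnV	tRNA	N	21	89
trnM	tRNA	J	191	261
trnI	tRNA	J	428	499
trnQ	tRNA	N	593	662
ND2	PCG	J	852	1832	ATT	TAA
trnW	tRNA	J	1841	1910
trnC	tRNA	N	1922	1991
trnY	tRNA	N	2110	2175
COI	PCG	J	2378	3910	ATG	TAA
trnL2	tRNA	J	4071	4141
COII	PCG	J	4142	4825	ATT	TAA
trnK	tRNA	J	5022	5091
trnD	tRNA	J	5328	5396
ATP8	PCG	J	5564	5747	ATA	T
ATP6	PCG	J	5749	6414	ATA	TAG
COIII	PCG	J	6506	7297	ATG	TAA
trnG	tRNA	J	7513	7577
ND3	PCG	J	7578	7931	ATT	TAA
trnA	tRNA	J	7989	8054
trnR	tRNA	J	8140	8213
trnN	tRNA	J	8421	8490
trnS1	tRNA	J	8488	8548
trnE	tRNA	J	8548	8615
trnF	tRNA	N	8608	8676
ND5	PCG	N	8690	10354	ATT	TAA
trnH	tRNA	N	10355	10427
ND4	PCG	N	10436	11782	ATA	TAG
ND4L	PCG	N	12030	12305	ATT	TAG
trnT	tRNA	J	12317	12386
trnP	tRNA	N	12388	12460
ND6	PCG	J	12545	13105	ATG	TAA
Cytb	PCG	J	13176	14294	ATG	TAA
trnS2	tRNA	J	14552	14621
ND1	PCG	N	14944	15891	ATA	TAA
trnL1	tRNA	N	16068	16138
lrRNA	rRNA	N	16360	17785
srRNA	rRNA	N	17881	18675
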