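chr1	0	124300000	p	n/a
chr1	124300000	247249719	q	n/a
chr2	0	93300000	p	n/a
chr2	93300000	242951149	q	n/a
chr3	0	91700000	p	n/a
chr3	91700000	199501827	q	n/a
chr4	0	50400000	p	n/a
chr4	50400000	191273063	q	n/a
chr5	0	47700000	p	n/a
chr5	47700000	180857866	q	n/a
chr6	0	60500000	p	n/a
chr6	60500000	170899992	q	n/a
chr7	0	59100000	p	n/a
chr7	59100000	158821424	q	n/a
chr8	0	45200000	p	n/a
chr8	45200000	146274826	q	n/a
chr9	0	51800000	p	n/a
chr9	51800000	140273252	q	n/a
chr10	0	40300000	p	n/a
chr10	40300000	135374737	q	n/a
chr11	0	52900000	p	n/a
chr11	52900000	134452384	q	n/a
chr12	0	35400000	p	n/a
chr12	35400000	132349534	q	n/a
chr13	0	16000000	p	n/a
chr13	16000000	114142980	q	n/a
chr14	0	15600000	p	n/a
chr14	15600000	106368585	q	n/a
chr15	0	15900000	p	n/a
chr15	15900000	100338915	q	n/a
chr16	0	38200000	p	n/a
chr16	38200000	88827254	q	n/a
chr17	0	22200000	p	n/a
chr17	22200000	78774742	q	n/a
chr18	0	16100000	p	n/a
chr18	16100000	76117153	q	n/a
chr19	0	28500000	p	n/a
chr19	28500000	63811651	q	n/a
chr20	0	27100000	p	n/a
chr20	27100000	62435964	q	n/a
chr21	0	12300000	p	n/a
chr21	12300000	46944323	q	n/a
chr22	0	14700000	p	n/a
chr22	14700000	49691432	q	n/a
chrX	0	59500000	p	n/a
chrX	59500000	154913754	q	n/a
chrY	0	11300000	p	n/a
chrY	11300000	57772954	q	n/a
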