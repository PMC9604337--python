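name	class	start	end	strand	start_codon	stop_codon	ign
trnI	tRNA	1	65	J			
trnQ	tRNA	63	130	N			-3
trnM	tRNA	153	221	J			22
nad2	PCG	230	1240	J	ATT	TAA	8
trnW	tRNA	1239	1303	J			-2
trnC	tRNA	1296	1357	N			-8
trnY	tRNA	1358	1426	N			
cox1	PCG	1428	2961	J	ATG	T	1
trnL2	tRNA	2962	3025	J			
cox2	PCG	3028	3709	J	ATG	T	2
trnK	tRNA	3710	3779	J			
trnD	tRNA	3779	3843	J			-1
atp8	PCG	3844	3999	J	ATT	TAA	
atp6	PCG	3996	4670	J	ATA	TAA	-4
cox3	PCG	4670	5453	J	ATG	T	-1
trnG	tRNA	5454	5516	J			
nad3	PCG	5517	5870	J	ATT	TAG	
trnA	tRNA	5869	5931	J			-2
trnR	tRNA	5931	5992	J			-1
trnN	tRNA	5994	6057	J			1
trnS1	tRNA	6058	6124	J			
trnE	tRNA	6135	6199	J			10
trnF	tRNA	6198	6262	N			-2
nad5	PCG	6263	7985	N	ATG	T	
trnH	tRNA	7987	8050	N			1
nad4	PCG	8051	9386	N	ATG	T	
nad4L	PCG	9380	9676	N	ATG	TAA	-7
trnT	tRNA	9679	9743	J			2
trnP	tRNA	9744	9808	N			
nad6	PCG	9829	10323	J	ATA	TAA	20
cytb	PCG	10323	11456	J	ATG	TAA	-1
trnS2	tRNA	11455	11523	J			-2
nad1	PCG	11555	12490	N	ATG	TAA	31
trnL1	tRNA	12492	12556	N			1
rrnL	rRNA	12557	13793	N			
trnV	tRNA	13794	13862	N			
rrnS	rRNA	13863	14638	N			
CR	CR	14639	15506	J			
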