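name	class	start	end	strand	start_codon	stop_codon	ign
trnI	tRNA	1	66	J			
trnQ	tRNA	64	131	N			-3
trnM	tRNA	159	226	J			27
nad2	PCG	228	1239	J	GTG	T	1
trnW	tRNA	1240	1304	J			
trnC	tRNA	1297	1358	N			-8
trnY	tRNA	1359	1427	N			
cox1	PCG	1429	2962	J	ATG	T	1
trnL2	tRNA	2963	3026	J			
cox2	PCG	3029	3710	J	ATG	T	2
trnK	tRNA	3711	3780	J			
trnD	tRNA	3780	3844	J			-1
atp8	PCG	3845	4000	J	ATT	TAA	
atp6	PCG	3994	4671	J	ATG	TAA	-7
cox3	PCG	4671	5454	J	ATG	T	-1
trnG	tRNA	5455	5517	J			
nad3	PCG	5518	5869	J	ATT	T	
trnA	tRNA	5870	5932	J			
trnR	tRNA	5932	5993	J			-1
trnN	tRNA	5995	6058	J			1
trnS1	tRNA	6059	6125	J			
trnE	tRNA	6136	6200	J			10
trnF	tRNA	6199	6263	N			-2
nad5	PCG	6264	7986	N	ATG	T	
trnH	tRNA	7988	8051	N			1
nad4	PCG	8052	9387	N	ATG	T	
nad4L	PCG	9381	9677	N	ATG	TAA	-7
trnT	tRNA	9680	9744	J			2
trnP	tRNA	9745	9809	N			
nad6	PCG	9812	10324	J	ATT	TAA	2
cytb	PCG	10324	11455	J	ATG	T	-1
trnS2	tRNA	11456	11524	J			
nad1	PCG	11556	12491	N	ATG	TAA	31
trnL1	tRNA	12493	12557	N			1
rrnL	rRNA	12558	13802	N			
trnV	tRNA	13803	13871	N			
rrnS	rRNA	13872	14596	N			
CR	CR	14597	15513	J			
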