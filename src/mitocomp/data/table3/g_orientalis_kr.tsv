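name	class	start	end	strand	start_codon	stop_codon	ign
trnI	tRNA	1	65	J			
trnQ	tRNA	63	130	N			-3
trnM	tRNA	153	221	J			22
nad2	PCG	223	1237	J	GTG	T	1
trnW	tRNA	1238	1305	J			
trnC	tRNA	1298	1359	N			-8
trnY	tRNA	1360	1425	N			
cox1	PCG	1427	2960	J	ATG	T	1
trnL2	tRNA	2961	3025	J			
cox2	PCG	3027	3708	J	ATG	T	1
trnK	tRNA	3709	3779	J			
trnD	tRNA	3779	3843	J			-1
atp8	PCG	3884	3999	J	ATT	TAA	
atp6	PCG	3993	4669	J	ATG	TA	-7
cox3	PCG	4670	5453	J	ATG	T	
trnG	tRNA	5454	5517	J			
nad3	PCG	5518	5869	J	ATT	T	
trnA	tRNA	5870	5932	J			
trnR	tRNA	5932	5993	J			-1
trnN	tRNA	5999	6062	J			5
trnS1	tRNA	6063	6129	J			
trnE	tRNA	6141	6205	J			11
trnF	tRNA	6204	6268	N			-2
nad5	PCG	6269	7991	N	ATG	T	
trnH	tRNA	7993	8058	N			1
nad4	PCG	8059	9394	N	ATG	T	
nad4L	PCG	9388	9684	N	ATG	TAA	-7
trnT	tRNA	9687	9750	J			2
trnP	tRNA	9751	9816	N			
nad6	PCG	9819	10330	J	ATT	TA	2
cytb	PCG	10331	11462	J	ATG	T	
trnS2	tRNA	11463	11530	J			
nad1	PCG	11565	12500	N	ATG	TAA	34
trnL1	tRNA	12502	12566	N			1
rrnL	rRNA	12567	13813	N			
trnV	tRNA	13814	13882	N			
rrnS	rRNA	13883	14601	N			
CR	CR	14602	15521	J			
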