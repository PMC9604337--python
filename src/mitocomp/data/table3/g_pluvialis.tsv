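name	class	start	end	strand	start_codon	stop_codon	ign
trnI	tRNA	1	65	J			
trnQ	tRNA	63	130	N			-3
trnM	tRNA	150	218	J			19
nad2	PCG	232	1237	J	ATT	T	13
trnW	tRNA	1238	1303	J			
trnC	tRNA	1296	1356	N			-8
trnY	tRNA	1357	1425	N			
cox1	PCG	1427	2960	J	ATG	T	1
trnL2	tRNA	2961	3025	J			
cox2	PCG	3027	3708	J	ATG	T	1
trnK	tRNA	3709	3778	J			
trnD	tRNA	3778	3847	J			-1
atp8	PCG	3857	4003	J	ATA	TAA	9
atp6	PCG	4000	4674	J	ATA	TAA	-4
cox3	PCG	4674	5457	J	ATG	T	-1
trnG	tRNA	5458	5520	J			
nad3	PCG	5530	5872	J	ATA	T	9
trnA	tRNA	5873	5935	J			
trnR	tRNA	5935	5996	J			-1
trnN	tRNA	6002	6066	J			5
trnS1	tRNA	6068	6132	J			1
trnE	tRNA	6149	6213	J			16
trnF	tRNA	6212	6276	N			-2
nad5	PCG	6277	7999	N	ATG	T	
trnH	tRNA	8001	8064	N			1
nad4	PCG	8065	9400	N	ATG	T	
nad4L	PCG	9394	9690	N	ATG	TAA	-7
trnT	tRNA	9693	9756	J			2
trnP	tRNA	9757	9821	N			
nad6	PCG	9842	10336	J	ATA	TAA	20
cytb	PCG	10336	11467	J	ATG	T	-1
trnS2	tRNA	11468	11536	J			
nad1	PCG	11569	12504	N	ATG	TAG	32
trnL1	tRNA	12506	12570	N			1
rrnL	rRNA	12571	13806	N			
trnV	tRNA	13807	13875	N			
rrnS	rRNA	13876	14658	N			
CR	CR	14659	15525	J			
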