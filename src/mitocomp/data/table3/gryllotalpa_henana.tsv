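name	class	start	end	strand	start_codon	stop_codon	ign
trnI	tRNA	1	66	J			
trnQ	tRNA	64	132	N			-3
trnM	tRNA	180	247	J			47
nad2	PCG	249	1256	J	GTG	TAA	-1
trnW	tRNA	1261	1325	J			4
trnC	tRNA	1318	1379	N			-8
trnY	tRNA	1379	1445	N			-1
cox1	PCG	1447	2980	J	ATG	T	1
trnL2	tRNA	2981	3045	J			
cox2	PCG	3046	3727	J	ATG	T	
trnK	tRNA	3728	3797	J			
trnD	tRNA	3797	3862	J			-1
atp8	PCG	3863	4018	J	ATT	TAA	
atp6	PCG	4012	4689	J	ATG	TAA	-7
cox3	PCG	4689	5472	J	ATG	T	-1
trnG	tRNA	5473	5535	J			
nad3	PCG	5536	5887	J	ATT	T	
trnA	tRNA	5888	5951	J			
trnR	tRNA	5951	6013	J			-1
trnN	tRNA	6015	6080	J			1
trnS1	tRNA	6081	6147	J			
trnE	tRNA	6149	6213	J			1
trnF	tRNA	6212	6276	N			-2
nad5	PCG	6277	7999	N	ATG	T	
trnH	tRNA	8003	8066	N			3
nad4	PCG	8067	9402	N	ATG	T	
nad4L	PCG	9396	9692	N	ATG	TAA	-7
trnT	tRNA	9695	9759	J			2
trnP	tRNA	9760	9824	N			
nad6	PCG	9827	10345	J	ATC	TAA	2
cytb	PCG	10345	11478	J	ATG	TAA	-1
trnS2	tRNA	11477	11540	J			-2
nad1	PCG	11569	12504	N	ATG	TAG	28
trnL1	tRNA	12506	12570	N			1
rrnL	rRNA	12554	13767	N			-17
trnV	tRNA	13839	13907	N			71
rrnS	rRNA	13909	14641	N			1
CR	CR	14642	15504	J			
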