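name	class	start	end	strand	start_codon	stop_codon	ign
trnI	tRNA	1	65	J			
trnQ	tRNA	63	130	N			-3
trnM	tRNA	148	216	J			17
nad2	PCG	218	1231	J	GTG	TAA	1
trnW	tRNA	1230	1293	J			-2
trnC	tRNA	1286	1346	N			-8
trnY	tRNA	1347	1415	N			
cox1	PCG	1419	2952	J	ATG	T	3
trnL2	tRNA	2953	3017	J			
cox2	PCG	3019	3700	J	ATG	T	1
trnK	tRNA	3701	3770	J			
trnD	tRNA	3770	3834	J			-1
atp8	PCG	3835	3990	J	ATT	TAA	
atp6	PCG	3984	4661	J	ATG	TAA	-7
cox3	PCG	4661	5444	J	ATG	T	-1
trnG	tRNA	5445	5507	J			
nad3	PCG	5508	5859	J	ATT	T	
trnA	tRNA	5860	5921	J			
trnR	tRNA	5922	5983	J			
trnN	tRNA	5989	6052	J			5
trnS1	tRNA	6053	6119	J			
trnE	tRNA	6135	6199	J			15
trnF	tRNA	6198	6262	N			-2
nad5	PCG	6263	7985	N	ATG	T	
trnH	tRNA	7987	8050	N			1
nad4	PCG	8051	9386	N	ATG	T	
nad4L	PCG	9380	9676	N	ATG	TAA	-7
trnT	tRNA	9679	9742	J			2
trnP	tRNA	9743	9807	N			
nad6	PCG	9810	10322	J	ATT	TAA	2
cytb	PCG	10322	11455	J	ATG	TAA	-1
trnS2	tRNA	11454	11522	J			-2
nad1	PCG	11548	12483	N	ATG	TAA	25
trnL1	tRNA	12485	12549	N			1
rrnL	rRNA	12550	13785	N			
trnV	tRNA	13786	13854	N			
rrnS	rRNA	13855	14584	N			
CR	CR	14585	15497	J			
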