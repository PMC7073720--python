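genus	species	mmetsp_code	n_sequences	min_contig_length	max_contig_length	n50
Akashiwo	sanguinea	MMETSP0223	380	150	593	197
Alexandrium	fundyense	MMETSP0196C	7872	150	2586	273
Alexandrium	margalefi	MMETSP0661	54023	150	7976	1055
Alexandrium	minutum	MMETSP0328	13126	150	2630	823
Alexandrium	tamarense	MMETSP0380
Alexandrium	tamarense	MMETSP0378	44911	150	5858	701
Alexandrium	tamarense	MMETSP0384	106664	150	13283	1398
Alexandrium	tamarense	MMETSP0382	98253	150	9488	1506
Amoebophrya	-	MMETSP0795	16699	150	35302	3178
Amphidinium	carterae	MMETSP0258	44378	150	13731	1899
Amphidinium	carterae	MMETSP0259	45656	150	9671	1781
Amphidinium	carterae	MMETSP0398C	7775	150	1411	225
Amphidinium	massartii	MMETSP0689	53416	150	11086	1897
Gambierdiscus	australes	MMETSP0766	53551	150	5938	1201
Glenodinium	foliaceum	MMETSP0118	80537	150	8317	1259
Glenodinium	foliaceum	MMETSP0119	89413	150	51794	950
Karenia	brevis	MMETSP0201	89316	150	24712	1642
Karenia	brevis	MMETSP0202	77716	150	23631	1298
Karenia	brevis	MMETSP0648	83137	150	28240	1563
Karenia	brevis	MMETSP0649	87365	150	24093	1566
Karenia	brevis	MMETSP0027	87338	150	20088	1514
Karenia	brevis	MMETSP0029	88007	150	17512	1524
Karenia	brevis	MMETSP0030	90601	150	15457	1493
Karenia	brevis	MMETSP0031	79230	150	11278	1499
Karenia	brevis	MMETSP0573	91547	150	24219	1728
Karenia	brevis	MMETSP0574	99942	150	19522	1792
Karenia	brevis	MMETSP0527	81513	150	14879	1664
Karenia	brevis	MMETSP0528	82936	150	18526	1658
Kryptoperidinium	foliaceum	MMETSP0120	93725	150	13985	1627
Kryptoperidinium	foliaceum	MMETSP0121	80158	150	5242	1190
Lingulodinium	polyedra	MMETSP1034	87027	150	9207	1260
Lingulodinium	polyedra	MMETSP1033	87335	150	15159	1339
Lingulodinium	polyedra	MMETSP1032	89450	150	11782	1331
Lingulodinium	polyedra	MMETSP1035	88741	150	22209	1427
Noctiluca	scintillans	MMETSP0253	45249	150	11484	1594
Pelagodinium	beii	MMETSP1338	55559	150	15296	1545
Polarella	glacialis	MMETSP0227	74437	150	23079	1587
Pyrocystis	lunula	MMETSP0229	572	150	1058	198
Scrippsiella	hangoei	MMETSP0359	81854	150	16784	1701
Scrippsiella	hangoei	MMETSP0361	83907	150	33299	1595
Scrippsiella	hangoei	MMETSP0360	69908	150	12551	1281
Togula	jolla	MMETSP0224	47727	150	8640	1570
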