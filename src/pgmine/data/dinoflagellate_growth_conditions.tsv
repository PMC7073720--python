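genus	species	mmetsp_code	strain	light	day_portion_h	phosphate_umol_kg	nitrate_umol	salinity_pct	note	geo_area
Akashiwo	sanguinea	MMETSP0223		3800	14	0.3	3	30		New York
Alexandrium	fundyense	MMETSP0196C		200	14	36.2	882	28		Atlantic Ocean
Alexandrium	margalefi	MMETSP0661		60	12		645	35		Tasmania
Alexandrium	minutum	MMETSP0328		100	12	36.2	882	25		Ria da Vigo
Alexandrium	tamarense	MMETSP0380		150	16	3.62	88.2	30		English Channel
Alexandrium	tamarense	MMETSP0378		150	16	3.62	88.2	30		English Channel
Alexandrium	tamarense	MMETSP0384		150	16	3.62	88.2	30		English Channel
Alexandrium	tamarense	MMETSP0382		150	16	3.62	88.2	30		English Channel
Amoebophrya	-	MMETSP0795		200	14	36.2	882	25		-
Amphidinium	carterae	MMETSP0258		60	12	60	60	28		Massachusetts USA
Amphidinium	carterae	MMETSP0259		60	12	60	N.I.	32		Massachusetts USA
Amphidinium	carterae	MMETSP0398C		200	14	36.2	882	32		Atlantic Ocean
Amphidinium	massartii	MMETSP0689		80	12	25	645	35		Pacific Ocean
Gambierdiscus	australes	MMETSP0766		80	14	25	645	35		Pacific Ocean
Glenodinium	foliaceum	MMETSP0118		550	12	36.2	882	21	Antibiotic	Chesapeake Bay
Glenodinium	foliaceum	MMETSP0119			48hr dark	36.2	882	21		Chesapeake Bay
Karenia	brevis	MMETSP0201	Wilson	50	16	36	883	36		Gulf of Mexico
Karenia	brevis	MMETSP0202	Wilson	50	16	36	883	36		Gulf of Mexico
Karenia	brevis	MMETSP0648	Wilson	70	12	36.2	882	35		Gulf of Mexico
Karenia	brevis	MMETSP0649	Wilson	70	12	36.2	882	27		Gulf of Mexico
Karenia	brevis	MMETSP0027	CCMP2229	60	12	60	60	32
Karenia	brevis	MMETSP0029	CCMP2229	60	12	60	N.I.	32
Karenia	brevis	MMETSP0030	CCMP2229	60	12	N.I.	60	32
Karenia	brevis	MMETSP0031	CCMP2229	600	12	60	60	32
Karenia	brevis	MMETSP0573	SP1	70	12	36.2	882	35
Karenia	brevis	MMETSP0574	SP1	70	12	36.2	882	27
Karenia	brevis	MMETSP0527	SP3	70	12	36.2	882	35
Karenia	brevis	MMETSP0528	SP3	70	12	36.2	882	27
Kryptoperidinium	foliaceum	MMETSP0120		550	12	36.2	882	21	Antibiotic	California USA
Kryptoperidinium	foliaceum	MMETSP0121			48 h dark	36.2	882	21	Antibiotic	California USA
Lingulodinium	polyedra	MMETSP1034		150	12	36.2	882	28		Gulf of Mexico
Lingulodinium	polyedra	MMETSP1033		150	12	36.2	882	28		Gulf of Mexico
Lingulodinium	polyedra	MMETSP1032		150	12	36.2	882	28		Gulf of Mexico
Lingulodinium	polyedra	MMETSP1035		150	12	36.2	882	28		Gulf of Mexico
Noctiluca	scintillans	MMETSP0253		3800	14	0.3	3	30		Puget Sound, WA
Pelagodinium	beii	MMETSP1338		40	12	36.2	882	35		Caribbean Sea
Polarella	glacialis	MMETSP0227		3800	14	0.3	3	30		McMurdo Sound
Pyrocystis	lunula	MMETSP0229		3800	14	0.3	3	30		-
Scrippsiella	hangoei	MMETSP0359		20	12	50	1000	6.5	Selenium 4.55 nMol/L	Baltic Sea
Scrippsiella	hangoei	MMETSP0360		20	12	36	883	3		Baltic Sea
Scrippsiella	hangoei	MMETSP0361		20	12	36	883	30		Baltic Sea
Togula	jolla	MMETSP0224		3800	14	0.3	3	30
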