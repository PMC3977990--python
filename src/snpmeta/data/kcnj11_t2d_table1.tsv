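study_id	year	ethnicity	design	n_cases	n_controls	maf_cases	maf_controls	ee_cases	ek_cases	kk_cases	ee_controls	ek_controls	kk_controls	n_trios	transmitted	untransmitted	bmi_cases	bmi_controls	age_cases	age_controls	pct_male_cases	pct_male_controls	hwe_p
Sakura	1996	Caucasian	population	133	82	0.30	0.30																0.05
Inoue	1997	Caucasian	population	291	164	0.34	0.34																>0.05
Hani	1998	Caucasian	population	191	114	0.49	0.37																0.95
Altshuler	2000	Caucasian	family	0	0									333									
Yamada	2001	East Asian	population	103	73	0.39	0.34																0.20
Gloyn 2001	2001	Caucasian	population	360	307	0.40	0.36																0.09
Florez	2004	Caucasian	population	1077	1077	0.47	0.61																0.71
Barroso	2003	Caucasian	population	499	494	0.38	0.34																0.82
Gloyn 2003	2003	Caucasian	both	854	1182	0.41	0.34							150									0.53
Hansen	2005	Caucasian	population	1164	4733	0.40	0.36																0.52
van Dam	2005	Caucasian	population	323	296	0.41	0.36																0.56
Yokoi	2006	East Asian	population	1590	1244	0.38	0.37																0.64
Liu	2006	East Asian	population	502	501	0.43	0.38																>0.05
Weedon	2006	Caucasian	population	2332	3592	0.38	0.35																>0.05
Sale	2007	Other	population	572	587	0.06	0.07																0.22
Koo	2007	East Asian	population	758	630	0.44	0.38																0.05
Sakamoto	2007	East Asian	population	906	889	0.39	0.34																0.72
Saxena	2007	Caucasian	population	5065	5785	0.49	0.47																>0.05
Vaxillaire	2007	Caucasian	population	287	2684	0.41	0.39																0.68
Scott	2007	Caucasian	population	2295	2363	0.49	0.46																0.72
Willer	2007	Caucasian	population	1087	953	0.49	0.44																0.32
Qi	2007	Caucasian	population	682	1078	0.40	0.35																0.38
Cejková	2007	Caucasian	population	172	113	0.37	0.37																0.26
Doi	2007	East Asian	population	550	2322	0.39	0.34																0.46
Lyssenko	2008	Caucasian	population	2201	16034	0.41	0.40																>0.05
Alsmadi	2008	Other	population	550	335	0.21	0.14																0.40
Takeuchi	2008	East Asian	population	7954	8809	0.38	0.35																0.91
Peng	2008	East Asian	population	275	168	0.69	0.57																>0.05
Bronstein	2008	Other	population	1131	1147	0.36	0.61																0.58
Sanghera	2008	Indian	population	532	374	0.34	0.38																0.45
Cauchi	2008	Caucasian	population	2734	4234	0.37	0.37																0.69
Ezzidi	2009	Other	population	805	503	0.32	0.29																0.56
Zhou	2009	East Asian	population	1848	1910	0.41	0.39																0.39
Chistiakov	2009	Caucasian	population	129	117	0.50	0.39																>0.05
Wang	2009	East Asian	population	396	387	0.46	0.37																0.46
Tabara	2009	East Asian	population	484	397	0.41	0.37																0.30
Thorsby	2009	Caucasian	population	750	1879	0.41	0.41																0.18
Hu	2009	East Asian	population	1849	1785	0.42	0.39																>0.05
Yamauchi	2010	East Asian	population	4470	3071	0.38	0.37																>0.05
Neuman	2010	Other	population	573	843	0.37	0.36																0.22
Chauhan	2010	Indian	population	2434	2403	0.39	0.32																0.41
Gupta	2010	Indian	population	209	179	0.40	0.47																0.12
Wen	2010	East Asian	population	1165	1135	0.41	0.40																0.10
Rees	2011	Indian	population	1663	1567	0.38	0.38																0.13
Chavali	2011	Indian	population	1017	1006	0.39	0.35																>0.05
Cheung	2011	Chinese	population	198	1185	0.33	0.33																0.41
Gamboa-Meléndez	2012	Other	population	1027	990	0.40	0.37																>0.05
Gonen	2012	Other	population	162	79	0.34	0.30																NA
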