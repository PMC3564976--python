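strain	ploidy	mat_a	mat_b	flags	country	locality
CZ2	dikaryon	A1;A2	B1;B3		Czech	Jihlava
Lmsa111007	dikaryon	A2;A3	B1		France	Brest
Lmsa110074	dikaryon	A1;A2			France	Lentillere
Lmsa110076	dikaryon	A3	B3		France	Commana
Lmsa110092	dikaryon	A1;A3	B2;B3		France	Buc
SL2	dikaryon		B4		Norway	Oslo
SL3	dikaryon	A2;A3	B1;B2		Germany	Bad Bevensen
SL4	dikaryon	A1;A3	B3;B4		Germany	Rothenburg
SL87	dikaryon	A1	B3;B4		Norway	Oslo
SL146	dikaryon	A3			Czech
SL160	dikaryon	A1;A3	B2;B4		Norway	Drammen
SL161	dikaryon	A3	B1;B3		Norway	Haugesund
SL164	dikaryon	A1;A3	B1;B4		Norway	Renneby
SL186	dikaryon	A1;A2;A3	B1;B2		England	Hampton Hill
SL200	dikaryon	A1;A3			Poland	Warsaw
SL203	dikaryon	A1;A2	B2;B4		England	London
SL204	dikaryon	A1;A2	B2;B4		Scotland	Glasgow
SL219	dikaryon	A2;A3	B2;B4		Finland	Helsinki
SL220	dikaryon	A2;A3	B1;B4		Finland	Manlyharju
SL223	dikaryon	A3	B2;B4		Finland	Pernio
SL224	dikaryon	A1;A2	B1;B3		Finland	Myrskyla
SL234	dikaryon	A1;A3	B1;B4		Belgium	Gembloux
SL236	dikaryon	A1;A2;A3	B1;B2		Belgium	Bruxelles
SL286	dikaryon	A1;A2;A3	B2;B3		Norway	Honefoss
SL290	dikaryon	A1;A3	B2;B3		Norway	Steinkjer
SL487	dikaryon	A1			Poland	Warsaw
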