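host	examined	infested	ip	ci_low	ci_high	mite	habitat	note
Caloenas nicobarica	4	2	50	9.8	90.2	Gunabopicobia lathami	contour
Chalcophaps indica	23	2	8.7	1.6	27.8	Meitingsunes chalcophas	coverts
Claravis pretiosa	10	3	30	8.7	61.9	Peristerophila claravis	coverts
Claravis pretiosa	10	2	20	3.7	55.3	Gunabopicobia claravis	contour
Columba arquatrix	4	2	50	9.8	90.2	Peristerophila columbae	under-wings cov.
Columba delegorguei	7	2	42	14.9	77.5	Meitingsunes lengai	under-tail cov.	ip;ci
Columba delegorguei	7	1	14.3	0.7	55.4	Gunabopicobia zumpti	contour
Columba guinea	4	2	50	9.8	90.2	Peristerophila columbae	under-wings cov.
Columba leucomela	1	1	100	5.0	100	Peristerophila leucomela	-
Columba leuconota	1	1	100	5.0	100	Peristerophila columbae	-
Columba livia	20	1	5	0.3	24.4	Peristerophila columbae	contour
Columba livia	NA	NA	NA	NA	NA	Gunabopicobia zumpti	contour
Columba livia	1	1	100	5.0	100	Meitingsunes zenadourae	covert
Columba livia	NA	NA	NA	NA	NA	Meitingsunes columbicus	secondaries
Columba oenas	NA	NA	NA	NA	NA	Meitingsunes columbicus	secondaries
Columba oenas	9	1	11.1	0.6	44.4	Peristerophila columbae	under-wings cov.
Columba palumbus	20	1	5	0.3	24.4	Meitingsunes columbicus	tail cov.
Columba palumbus	20	1	5	0.3	24.4	Peristerophila columbae	covert
Columba trocaz	1	1	100	5.0	100	Peristerophila columbae	under wing cov.
Columbina minuta	4	2	50	9.8	90.2	Peristerophila mucuya	contour
Columbina passerina	15	2	13.3	2.4	39.7	Peristerophila mucuya	secondaries
Columbina talpacoti	32	8	25	12.2	42.3	Peristerophila mucuya	under-wings cov
Columbina squammata	11	1	9.1	0.5	40.5	Peristerophila mucuya	tertials
Ducula bicolor	2	2	100	22.4	100	Gunabopicobia masalaje	contour
Ducula luctuosa	1	1	100	22.4	100	Gunabopicobia masalaje	contour	ci
Ducula luctuosa	1	1	100	22.4	100	Peristerophila lature	covert	ci
Ducula pistrinaria	2	1	50	2.5	97.5	Gunabopicobia masalaje	contour
Ducula rosacea	1	1	100	22.4	100	Gunabopicobia masalaje	contour	ci
Ducula rufigaster	1	1	100	22.4	100	Gunabopicobia masalaje	contour	ci
Ducula spilorrhoa	1	1	100	5.0	100	Gunabopicobia masalaje	contour
Ducula spilorrhoa	1	1	100	5.0	100	Peristerophila lature	-
Gallicolumba luzonica	2	1	50	2.5	97.5	Meitingsunes turacoenas	contour
Geopelia cuneata	2	1	50	2.5	97.5	Peristerophila geopelis	covert
Geopelia placida	2	1	50	2.5	97.5	Peristerophila geopelis	contour
Geopelia striata	13	5	38.5	16.6	65.8	Peristerophila geopelis	covert
Geotrygon chrysia	1	1	100	22.4	100	Gunabopicobia geotrygoni	contour	ci
Geotrygon chiriquensis	1	1	100	5	100	Peristerophila columbae	under-tail cov.
Geotrygon frenata	3	1	33	1.7	86.5	Meitingsunes zenadourae	-	ip
Geotrygon frenata	3	1	33	1.7	86.5	Gunabopicobia geotrygoni	contour	ip
Geotrygon linearis	8	1	12.5	0.6	50	Gunabopicobia geotrygoni	contour
Geotrygon linearis	8	1	12.5	0.6	50	Terratosyringophilus geotrygonus	primaries
Geotrygon montana	8	2	25	4.6	63.5	Gunabopicobia geotrygoni	contour
Geotrygon montana	8	1	12.5	0.6	50	Psittaciphilus montanus	under tail cov.
Leptotila verreauxi	24	1	4.2	0.2	20.4	Meitingsunes zenadourae	under-tail cov.
Leptotila verreauxi	24	1	4.2	0.2	20.4	Gunabopicobia leptotila	contour
Leptotila rufaxilla	10	2	20	3.7	55.3	Meitingsunes zenadourae	under-tail cov.
Leucosarcia melanoleuca	1	1	100	5	100	Gunabopicobia lathami	contour
Macropygia amboinensis	6	1	16.7	0.9	58.9	Meitingsunes turacoenas	-
Macropygia phasianella	14	3	21.4	6.1	50	Meitingsunes turacoenas	under and upper-tail cov.
Macropygia unchall	3	2	66.7	13.5	98.3	Meitingsunes turacoenas	under-tail cov.
Metriopelia ceciliae	2	1	50	2.5	97.5	Peristerophila mucuya	secondaries, covert
Metriopelia melanoptera	8	1	12.5	0.6	50	Gunabopicobia metriopelia	contour
Ocyphaps lophotes	1	1	100	5	100	Peristerophila geopelis	small covert, under-tail cov.
Oena capensis	17	5	29.4	12.4	54.4	Peristerophila claravis	under-tail cov.
Patagioenas fasciata	1	1	100	5.0	100	Psittaciphilus patagioenas	upper-tail cov.
Patagioenas picazuro	16	2	12.5	2.3	37.2	Meitingsunes zenadourae	under-wing cov.
Patagioenas picazuro	16	1	6.2	0.3	30.5	Gunabopicobia zumpti	contour
Patagioenas speciosa	8	1	12.5	0.6	50	Peristerophila columbae	-
Patagioenas speciosa	8	1	12.5	0.6	50	Gunabopicobia zumpti	contour
Patagioenas speciosa	8	1	12.5	0.6	50	Psittaciphilus patagioenas	coverts
Ptilinopus iozonus	4	1	25	1.3	75.1	Gunabopicobia masalaje	contour
Ptilinopus jambu	5	1	20	1	65.7	Peristerophila lature	coverts
Ptilinopus magnificus	17	2	11.8	2.1	35	Meitingsunes ptilinopus	under-tail cov.
Ptilinopus melanospilus	3	2	66.7	13.5	98.3	Peristerophila lature	coverts
Ptilinopus regina	4	1	25	1.3	75.1	Peristerophila lature	coverts
Ptilinopus rivoli	1	1	100	5	100	Meitingsunes ptilinopus	under-tail cov.
Streptopelia decaocto	12	2	16.7	3	45.7	Peristerophila columbae	secondaries
Streptopelia capicola	NA	NA	NA	NA	NA	Gunabopicobia zumpti	contour
Streptopelia orientalis	22	2	9.1	1.6	29.1	Meitingsunes lengai	under-tail cov.
Streptopelia semitorquata	21	1	4.8	0.2	23.3	Meitingsunes lengai	rectrices
Streptopelia semitorquata	21	1	4.8	0.2	23.3	Gunabopicobia zumpti	contour
Streptopelia semitorquata	21	3	14.3	4	35.4	Peristerophila columbae	coverts
Streptopelia turtur	30	4	13.3	4.7	29.8	Peristerophila columbae	contour, under-tail cov.
Treron waalia	1	1	100	5.0	100	Meitingsunes columbicus	covert
Turacoena manadensis	4	1	25	1.3	75.1	Meitingsunes turacoenas	under tail cov
Turacoena modesta	5	1	20	1	65.7	Meitingsunes turacoenas	under tail cov
Turtur chalcospilos	13	1	7	0.4	34.2	Meitingsunes tympanistria	coverts	ip
Turtur tympanistria	12	2	16.7	3	45.7	Meitingsunes tympanistria	rectrices
Zenaida asiatica	NA	NA	NA	NA	NA	Meitingsunes zenadourae	-
Zenaida asiatica	NA	NA	NA	NA	NA	Terratosyringophilus longisoma	-
Zenaida auriculata	NA	NA	NA	NA	NA	Meitingsunes zenadourae	-
Zenaida macroura	1	1	100	5	100	Meitingsunes zenadourae	coverts
Zenaida macroura	NA	NA	NA	NA	NA	Terratosyringophilus longisoma	primaries
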