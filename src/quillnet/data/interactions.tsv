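mite	host	regions
Meitingsunes adwelles	Geotrygon frenata	Neot
Meitingsunes columbicus	Columba oenas	Pala
Meitingsunes columbicus	Columba livia	Pala
Meitingsunes columbicus	Columba palumbus	Pala
Meitingsunes columbicus	Treron waalia	Afro
Meitingsunes chalcophas	Chalcophaps indica	Orie;Aust
Meitingsunes ptilinopus	Ptilinopus magnificus	Aust
Meitingsunes ptilinopus	Ptilinopus rivoli	Ocea
Meitingsunes lengai	Columba delegorguei	Afro
Meitingsunes lengai	Streptopelia orientalis	Afro
Meitingsunes lengai	Streptopelia semitorquata	Pala
Meitingsunes turacoenas	Gallicolumba luzonica	Orie
Meitingsunes turacoenas	Macropygia amboinensis	Ocea
Meitingsunes turacoenas	Macropygia phasianella	Orie
Meitingsunes turacoenas	Macropygia unchall	Ocea
Meitingsunes turacoenas	Turacoena manadensis	Orie
Meitingsunes turacoenas	Turacoena modesta	Orie
Meitingsunes tympanistria	Turtur chalcospilos	Afro
Meitingsunes tympanistria	Turtur tympanistria	Afro
Meitingsunes zenadourae	Columba livia	Near;Afro
Meitingsunes zenadourae	Geotrygon frenata	Neot
Meitingsunes zenadourae	Leptotila rufaxilla	Neot
Meitingsunes zenadourae	Leptotila verreauxi	Neot
Meitingsunes zenadourae	Patagioenas picazuro	Neot
Meitingsunes zenadourae	Zenaida asiatica	Near
Meitingsunes zenadourae	Zenaida auriculata	Neot
Meitingsunes zenadourae	Zenaida macroura	Near
Peristerophila columbae	Columba arquatrix	Afro
Peristerophila columbae	Columba guinea	Afro
Peristerophila columbae	Columba leuconota	Orie
Peristerophila columbae	Columba livia	Pala;Near;Orie;Sa-Arab
Peristerophila columbae	Columba oenas	Pala
Peristerophila columbae	Columba palumbus	Pala
Peristerophila columbae	Columba trocaz	Pala
Peristerophila columbae	Geotrygon chiriquensis	Pana
Peristerophila columbae	Patagioenas speciosa	Neot
Peristerophila columbae	Streptopelia capicola	Afro
Peristerophila columbae	Streptopelia decaocto	Sa-Arab
Peristerophila columbae	Streptopelia orientalis	Orie
Peristerophila columbae	Streptopelia semitorquata	Afro
Peristerophila columbae	Streptopelia tranquebarica	Orie
Peristerophila columbae	Streptopelia turtur	Pala
Peristerophila claravis	Claravis pretiosa	Neot;Pana
Peristerophila claravis	Oena capensis	Afro
Peristerophila geopelis	Geopelia cuneata	Aust
Peristerophila geopelis	Geopelia placida	Aust
Peristerophila geopelis	Geopelia striata	Orie
Peristerophila geopelis	Ocyphaps lophotes	Aust
Peristerophila lature	Ducula luctuosa	Aust
Peristerophila lature	Ducula spilorrhoa	Aust
Peristerophila lature	Ptilinopus melanospilus	Orie
Peristerophila lature	Ptilinopus porphyreus	Orie
Peristerophila lature	Ptilinopus regina	Orie
Peristerophila leucomela	Columba leucomela	Aust
Peristerophila mucuya	Columbina minuta	Neot
Peristerophila mucuya	Columbina passerina	Neot;Near
Peristerophila mucuya	Columbina squammata	Neot
Peristerophila mucuya	Columbina talpacoti	Neot;Pala
Peristerophila mucuya	Metriopelia ceciliae	Neot
Peristerophila mucuya	Metriopelia melanoptera	Neot
Peristerophila mucuya	Streptopelia decaocto
Peristerophila mucuya	Brotogeris versicolurus	Neot
Peristerophila mucuya	Psilopsiagon aymara	Neot
Peristerophila mucuya	Trichoglossus haematodus	Orie
Psittaciphilus montanus	Geotrygon montana	Neot;Pana
Psittaciphilus patagioenas	Patagioenas fasciata	Neot
Psittaciphilus patagioenas	Patagioenas speciosa	Neot
Terratosyringophilus geotrygonus	Geotrygon linearis	Neot
Terratosyringophilus longisoma	Zenaida asiatica	Near
Terratosyringophilus longisoma	Zenaida macroura	Near
Gunabopicobia claravis	Claravis pretiosa	Neot
Gunabopicobia geotrygoni	Geotrygon linearis	Neot
Gunabopicobia geotrygoni	Geotrygon chrysia	Ocea
Gunabopicobia geotrygoni	Geotrygon frenata	Neot
Gunabopicobia geotrygoni	Geotrygon montana	Neot
Gunabopicobia masalaje	Ducula bicolor	Orie
Gunabopicobia masalaje	Ducula rufigaster	Ocea
Gunabopicobia masalaje	Ducula rosacea	Orie
Gunabopicobia masalaje	Ducula pistrinaria	Ocea
Gunabopicobia masalaje	Ducula spilorrhoa	Orie
Gunabopicobia masalaje	Ducula luctuosa	Ocea
Gunabopicobia masalaje	Ptilinopus iozonus	Ocea
Gunabopicobia metriopelia	Metriopelia melanoptera	Neot
Gunabopicobia lathami	Leucosarcia melanoleuca	Orie;Ocea
Gunabopicobia lathami	Caloenas nicobarica	Orie;Ocea
Gunabopicobia leptotila	Leptotila verreauxi	Neot
Gunabopicobia zumpti	Columba livia	Near;Pala
Gunabopicobia zumpti	Columba delegorguei	Afro
Gunabopicobia zumpti	Patagioenas picazuro	Neot
Gunabopicobia zumpti	Patagioenas speciosa	Neot
Gunabopicobia zumpti	Streptopelia capicola	Afro
Gunabopicobia zumpti	Streptopelia semitorquata	Afro
Gunabopicobia zumpti	Streptopelia senegalensis	Afro
Gunabopicobia zumpti	Zenaida macroura	Near
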