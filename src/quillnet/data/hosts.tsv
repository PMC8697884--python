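species	genus	subfamily	order
Caloenas nicobarica	Caloenas	Raphinae	Columbiformes
Chalcophaps indica	Chalcophaps	Raphinae	Columbiformes
Claravis pretiosa	Claravis	Claravinae	Columbiformes
Columba arquatrix	Columba	Columbinae	Columbiformes
Columba delegorguei	Columba	Columbinae	Columbiformes
Columba guinea	Columba	Columbinae	Columbiformes
Columba leucomela	Columba	Columbinae	Columbiformes
Columba leuconota	Columba	Columbinae	Columbiformes
Columba livia	Columba	Columbinae	Columbiformes
Columba oenas	Columba	Columbinae	Columbiformes
Columba palumbus	Columba	Columbinae	Columbiformes
Columba trocaz	Columba	Columbinae	Columbiformes
Columbina minuta	Columbina	Claravinae	Columbiformes
Columbina passerina	Columbina	Claravinae	Columbiformes
Columbina squammata	Columbina	Claravinae	Columbiformes
Columbina talpacoti	Columbina	Claravinae	Columbiformes
Ducula bicolor	Ducula	Raphinae	Columbiformes
Ducula luctuosa	Ducula	Raphinae	Columbiformes
Ducula pistrinaria	Ducula	Raphinae	Columbiformes
Ducula rosacea	Ducula	Raphinae	Columbiformes
Ducula rufigaster	Ducula	Raphinae	Columbiformes
Ducula spilorrhoa	Ducula	Raphinae	Columbiformes
Gallicolumba luzonica	Gallicolumba	Raphinae	Columbiformes
Geopelia cuneata	Geopelia	Raphinae	Columbiformes
Geopelia placida	Geopelia	Raphinae	Columbiformes
Geopelia striata	Geopelia	Raphinae	Columbiformes
Geotrygon chiriquensis	Geotrygon	Columbinae	Columbiformes
Geotrygon chrysia	Geotrygon	Columbinae	Columbiformes
Geotrygon frenata	Geotrygon	Columbinae	Columbiformes
Geotrygon linearis	Geotrygon	Columbinae	Columbiformes
Geotrygon montana	Geotrygon	Columbinae	Columbiformes
Leptotila rufaxilla	Leptotila	Columbinae	Columbiformes
Leptotila verreauxi	Leptotila	Columbinae	Columbiformes
Leucosarcia melanoleuca	Leucosarcia	Raphinae	Columbiformes
Macropygia amboinensis	Macropygia	Columbinae	Columbiformes
Macropygia phasianella	Macropygia	Columbinae	Columbiformes
Macropygia unchall	Macropygia	Columbinae	Columbiformes
Metriopelia ceciliae	Metriopelia	Claravinae	Columbiformes
Metriopelia melanoptera	Metriopelia	Claravinae	Columbiformes
Ocyphaps lophotes	Ocyphaps	Raphinae	Columbiformes
Oena capensis	Oena	Raphinae	Columbiformes
Patagioenas fasciata	Patagioenas	Columbinae	Columbiformes
Patagioenas picazuro	Patagioenas	Columbinae	Columbiformes
Patagioenas speciosa	Patagioenas	Columbinae	Columbiformes
Ptilinopus iozonus	Ptilinopus	Raphinae	Columbiformes
Ptilinopus jambu	Ptilinopus	Raphinae	Columbiformes
Ptilinopus magnificus	Ptilinopus	Raphinae	Columbiformes
Ptilinopus melanospilus	Ptilinopus	Raphinae	Columbiformes
Ptilinopus porphyreus	Ptilinopus	Raphinae	Columbiformes
Ptilinopus regina	Ptilinopus	Raphinae	Columbiformes
Ptilinopus rivoli	Ptilinopus	Raphinae	Columbiformes
Streptopelia capicola	Streptopelia	Columbinae	Columbiformes
Streptopelia decaocto	Streptopelia	Columbinae	Columbiformes
Streptopelia orientalis	Streptopelia	Columbinae	Columbiformes
Streptopelia semitorquata	Streptopelia	Columbinae	Columbiformes
Streptopelia senegalensis	Streptopelia	Columbinae	Columbiformes
Streptopelia tranquebarica	Streptopelia	Columbinae	Columbiformes
Streptopelia turtur	Streptopelia	Columbinae	Columbiformes
Treron waalia	Treron	Raphinae	Columbiformes
Turacoena manadensis	Turacoena	Columbinae	Columbiformes
Turacoena modesta	Turacoena	Columbinae	Columbiformes
Turtur chalcospilos	Turtur	Raphinae	Columbiformes
Turtur tympanistria	Turtur	Raphinae	Columbiformes
Zenaida asiatica	Zenaida	Columbinae	Columbiformes
Zenaida auriculata	Zenaida	Columbinae	Columbiformes
Zenaida macroura	Zenaida	Columbinae	Columbiformes
Brotogeris versicolurus	Brotogeris	Psittacidae	Psittaciformes
Psilopsiagon aymara	Psilopsiagon	Psittacidae	Psittaciformes
Trichoglossus haematodus	Trichoglossus	Psittaculidae	Psittaciformes
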