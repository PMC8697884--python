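species	examined
Chalcophaps stephani	2
Claravis mondetoura	2
Columba rupestris	11
Columbina cruziana	2
Ducula aenea	4
Ducula carola	2
Ducula concinna	1
Ducula finschii	2
Ducula perspicillata	1
Ducula zoeae	7
Gallicolumba rufigula	1
Geotrygon violacea	1
Gymnophaps albertisii	2
Henicophaps albifrons	1
Henicophaps foersteri	1
Leptotila cassini	1
Leptotrygon veraguensis	1
Macropygia magna	3
Macropygia ruficeps	4
Otidiphaps nobilis	1
Patagioenas raucana	12
Patagioenas cayennensis	18
Patagioenas oenops	4
Patagioenas subvinacea	3
Ptilinopus bernsteinii	1
Ptilinopus cinctus	6
Ptilinopus coronulatus	4
Ptilinopus ornatus	1
Ptilinopus porphyreus	3
Ptilinopus pulchellus	5
Ptilinopus solomonensis	1
Ptilinopus superbus	6
Reinwardtoena reinwardtii	2
Streptopelia picturata	1
Streptopelia roseogrisea	3
Streptopelia senegalensis	26
Streptopelia tranquebarica	5
Treron bicinctus	3
Treron calva	7
Treron capellei	3
Treron curvirostra	8
Treron delalandii	20
Treron fulvicollis	4
Treron olax	2
Treron pompadora	7
Treron sieboldii	5
Treron sphenurus	3
Treron vernanus	18
Zenaida galapagoensis	8
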