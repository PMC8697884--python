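host	mite	subfamily	niche
Claravis pretiosa	Gunabopicobia claravis	P	contour
Claravis pretiosa	Peristerophila claravis	S	covert
Columba palumbus	Meitingsunes columbicus	S	secondaries
Columba palumbus	Peristerophila columbae	S	covert
Ducula spilorrhoa	Gunabopicobia masalaje	P	contour
Ducula spilorrhoa	Peristerophila lature	S	covert
Ducula luctuosa	Gunabopicobia masalaje	P	contour
Ducula luctuosa	Peristerophila lature	S	covert
Geotrygon frenata	Gunabopicobia geotrygoni	P	contour
Geotrygon frenata	Meitingsunes zenadourae	S	under-wing covert
Geotrygon montana	Gunabopicobia geotrygoni	P	contour
Geotrygon montana	Psittaciphilus montanus	S	under-tail covert
Leptotila verreauxi	Gunabopicobia leptotila	P	contour
Leptotila verreauxi	Meitingsunes zenadourae	S	under-tail covert
Metriopelia melanoptera	Gunabopicobia metriopelia	P	contour
Metriopelia melanoptera	Peristerophila mucuya	S	covert
Patagioenas picazuro	Gunabopicobia zumpti	P	contour
Patagioenas picazuro	Meitingsunes zenadourae	S	under-wing covert
Patagioenas speciosa	Gunabopicobia zumpti	P	contour
Patagioenas speciosa	Peristerophila columbae	S	covert
Patagioenas speciosa	Psittaciphilus patagioenas	S	covert
Streptopelia semitorquata	Gunabopicobia zumpti	P	contour
Streptopelia semitorquata	Meitingsunes lengai	S	rectrices
Streptopelia semitorquata	Peristerophila columbae	S	covert
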