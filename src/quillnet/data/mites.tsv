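species	genus	subfamily
Meitingsunes adwelles	Meitingsunes	Syringophilinae
Meitingsunes chalcophas	Meitingsunes	Syringophilinae
Meitingsunes columbicus	Meitingsunes	Syringophilinae
Meitingsunes lengai	Meitingsunes	Syringophilinae
Meitingsunes ptilinopus	Meitingsunes	Syringophilinae
Meitingsunes turacoenas	Meitingsunes	Syringophilinae
Meitingsunes tympanistria	Meitingsunes	Syringophilinae
Meitingsunes zenadourae	Meitingsunes	Syringophilinae
Peristerophila claravis	Peristerophila	Syringophilinae
Peristerophila columbae	Peristerophila	Syringophilinae
Peristerophila geopelis	Peristerophila	Syringophilinae
Peristerophila lature	Peristerophila	Syringophilinae
Peristerophila leucomela	Peristerophila	Syringophilinae
Peristerophila mucuya	Peristerophila	Syringophilinae
Psittaciphilus montanus	Psittaciphilus	Syringophilinae
Psittaciphilus patagioenas	Psittaciphilus	Syringophilinae
Terratosyringophilus geotrygonus	Terratosyringophilus	Syringophilinae
Terratosyringophilus longisoma	Terratosyringophilus	Syringophilinae
Gunabopicobia claravis	Gunabopicobia	Picobiinae
Gunabopicobia geotrygoni	Gunabopicobia	Picobiinae
Gunabopicobia lathami	Gunabopicobia	Picobiinae
Gunabopicobia leptotila	Gunabopicobia	Picobiinae
Gunabopicobia masalaje	Gunabopicobia	Picobiinae
Gunabopicobia metriopelia	Gunabopicobia	Picobiinae
Gunabopicobia zumpti	Gunabopicobia	Picobiinae
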