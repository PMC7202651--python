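tribe	genus	pd	n_otus
Edmontosaurini	Edmontosaurus	0.0224	3
Edmontosaurini	Kamuysaurus	0.0102	1
Edmontosaurini	Kerberosaurus	0.0050	1
Edmontosaurini	Laiyangosaurus	0.0126	1
Edmontosaurini	Shantungosaurus	0.0086	1
Kritosaurini	Kritosaurus	0.0077	1
Kritosaurini	Gryposaurus	0.0296	3
Kritosaurini	Rhinorex	0.0095	1
Kritosaurini	Secernosaurus	0.0059	1
Saurolophini	Saurolophus	0.0210	2
Saurolophini	Lophorhothon	0.0062	1
Saurolophini	Prosaurolophus	0.0063	1
Brachylophosaurini	Acristavus	0.0097	1
Brachylophosaurini	Brachylophosaurus	0.0129	1
Brachylophosaurini	Maiasaura	0.0131	1
Brachylophosaurini	Probrachylophosaurus	0.0138	1
Brachylophosaurini	Wulagasaurus	0.0147	1
Brachylophosaurini	Hadrosaurus	0.0101	1
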