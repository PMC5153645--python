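sequence	amidated	frequency	name	group_or_species
CYIQNCPLG	true	0	oxytocin	mammals
CYFQNCPRG	true	0	vasopressin	mammals
CYIQNCPRG	true	0	vasotocin	non-mammalian vertebrates
CLITNCPRG	true	57	inotocin	insects
CFITNCPPG	true	32	inotocin-like	arthropods
CLITNCPKG	true	8	inotocin-like	insects
CFITNCPIG	true	3		Symphylella vulgaris, Metaseiulus occidentalis, Varroa destructor
CLIINCPRG	true	2		Athalia rosae, Neodiprion lecontei
CLITNCPIG	true	2		Haploembia palaui, Leptinotarsa decemlineata
CFISNCPVS	true	2		Calanus finmarchicus
CMIINCPRG	true	2		Gryllotalpa sp., Teleogryllus commodus
CFITNCPRA	true	1		Dermatophagoides farinae
CFITNCPPA	true	1		Sarcoptes scabiei
CFITNCPSG	true	1		Tigriopus californicus
CLIVNCPRG	true	1		Camponotus floridanus
CLITNCPHG	true	1		Dinoponera quadriceps
CYITNCPWG	true	1		Arachnocampa luminosa
CLISNCPKG	true	1		Pachypsylla venusta
CLINNCPTG	true	1		Diaphorina citri
CYITNCPPG	true	1		Strigamia maritima
CFILDCPLM	false	1		Speleonectes cf. tulumensis
CYIINCIDND	true	1		Scolopendra subspinipes
CFITNCPVGG	true	1		Lepeophtheirus salmonis
CFITNCPVGS	true	1		Caligus rogercresseyi
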