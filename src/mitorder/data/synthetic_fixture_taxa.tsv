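# SYNTHETIC taxon registry: a constructed 65-species / 14-family snake
# panel standing in for the study panel this pipeline is designed for.
# Species names are real snake taxa with published mitogenomes, but the
# per-species arrangement assignments below are a synthetic reconstruction
# chosen so that the panel reproduces the published distribution:
# 11 arrangement types; Type I in Leptotyphlopidae, II in Typhlopidae;
# III-A only in Tropidophis haetianus; III-B throughout Viperidae except
# Ovophis okinavensis (III-B1); III-C in six independent colubrid/
# homalopsid lineages; III-D only in Ophiophagus hannah; III-E/F/G in
# Imantodes cenchoa / Leptodeira septentrionalis / Sibon nebulatus.
taxon_id	species	family	type_label
Leptotyphlops_dulcis	Leptotyphlops dulcis	Leptotyphlopidae	I
Rena_humilis	Rena humilis	Leptotyphlopidae	I
Indotyphlops_braminus	Indotyphlops braminus	Typhlopidae	II
Amerotyphlops_reticulatus	Amerotyphlops reticulatus	Typhlopidae	II
Xerotyphlops_vermicularis	Xerotyphlops vermicularis	Typhlopidae	II
Anilius_scytale	Anilius scytale	Aniliidae	III
Tropidophis_haetianus	Tropidophis haetianus	Tropidophiidae	III-A
Cylindrophis_ruffus	Cylindrophis ruffus	Cylindrophiidae	III
Xenopeltis_unicolor	Xenopeltis unicolor	Xenopeltidae	III
Python_regius	Python regius	Pythonidae	III
Python_bivittatus	Python bivittatus	Pythonidae	III
Malayopython_reticulatus	Malayopython reticulatus	Pythonidae	III
Boa_constrictor	Boa constrictor	Boidae	III
Eunectes_notaeus	Eunectes notaeus	Boidae	III
Candoia_aspera	Candoia aspera	Boidae	III
Calabaria_reinhardtii	Calabaria reinhardtii	Boidae	III
Acrochordus_granulatus	Acrochordus granulatus	Acrochordidae	III
Achalinus_meiguensis	Achalinus meiguensis	Xenodermatidae	III
Azemiops_feae	Azemiops feae	Viperidae	III-B
Daboia_russelii	Daboia russelii	Viperidae	III-B
Deinagkistrodon_acutus	Deinagkistrodon acutus	Viperidae	III-B
Ovophis_monticola	Ovophis monticola	Viperidae	III-B
Ovophis_okinavensis	Ovophis okinavensis	Viperidae	III-B1
Gloydius_brevicaudus	Gloydius brevicaudus	Viperidae	III-B
Gloydius_intermedius	Gloydius intermedius	Viperidae	III-B
Protobothrops_mucrosquamatus	Protobothrops mucrosquamatus	Viperidae	III-B
Protobothrops_flavoviridis	Protobothrops flavoviridis	Viperidae	III-B
Trimeresurus_albolabris	Trimeresurus albolabris	Viperidae	III-B
Agkistrodon_piscivorus	Agkistrodon piscivorus	Viperidae	III-B
Crotalus_horridus	Crotalus horridus	Viperidae	III-B
Enhydris_plumbea	Enhydris plumbea	Homalopsidae	III-C
Homalopsis_buccata	Homalopsis buccata	Homalopsidae	III-C
Bungarus_fasciatus	Bungarus fasciatus	Elapidae	III
Bungarus_multicinctus	Bungarus multicinctus	Elapidae	III
Ophiophagus_hannah	Ophiophagus hannah	Elapidae	III-D
Naja_atra	Naja atra	Elapidae	III
Naja_naja	Naja naja	Elapidae	III
Micrurus_fulvius	Micrurus fulvius	Elapidae	III
Laticauda_colubrina	Laticauda colubrina	Elapidae	III
Hydrophis_cyanocinctus	Hydrophis cyanocinctus	Elapidae	III
Ahaetulla_prasina	Ahaetulla prasina	Colubridae	III
Boiga_kraepelini	Boiga kraepelini	Colubridae	III
Imantodes_cenchoa	Imantodes cenchoa	Colubridae	III-E
Leptodeira_septentrionalis	Leptodeira septentrionalis	Colubridae	III-F
Sibon_nebulatus	Sibon nebulatus	Colubridae	III-G
Rhabdophis_tigrinus	Rhabdophis tigrinus	Colubridae	III
Sinonatrix_percarinata	Sinonatrix percarinata	Colubridae	III
Thermophis_baileyi	Thermophis baileyi	Colubridae	III
Lycodon_ruhstrati	Lycodon ruhstrati	Colubridae	III
Lycodon_rufozonatum	Lycodon rufozonatum	Colubridae	III-C
Lycodon_semicarinatus	Lycodon semicarinatus	Colubridae	III-C
Lycodon_flavozonatum	Lycodon flavozonatum	Colubridae	III-C
Hierophis_viridiflavus	Hierophis viridiflavus	Colubridae	III
Ptyas_dhumnades	Ptyas dhumnades	Colubridae	III
Ptyas_korros	Ptyas korros	Colubridae	III-C
Ptyas_mucosa	Ptyas mucosa	Colubridae	III-C
Coelognathus_radiatus	Coelognathus radiatus	Colubridae	III
Euprepiophis_perlacea	Euprepiophis perlacea	Colubridae	III-C
Euprepiophis_mandarinus	Euprepiophis mandarinus	Colubridae	III-C
Elaphe_anomala	Elaphe anomala	Colubridae	III
Elaphe_bimaculata	Elaphe bimaculata	Colubridae	III-C
Elaphe_davidi	Elaphe davidi	Colubridae	III-C
Oocatochus_rufodorsatus	Oocatochus rufodorsatus	Colubridae	III-C
Orthriophis_taeniurus	Orthriophis taeniurus	Colubridae	III
Pantherophis_guttatus	Pantherophis guttatus	Colubridae	III
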