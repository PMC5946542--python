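((Leptotyphlops_dulcis,Rena_humilis),(Indotyphlops_braminus,(Amerotyphlops_reticulatus,Xerotyphlops_vermicularis)),((Anilius_scytale,Tropidophis_haetianus),(((Xenopeltis_unicolor,(Python_regius,(Python_bivittatus,Malayopython_reticulatus))),(Cylindrophis_ruffus,((Boa_constrictor,Eunectes_notaeus),(Candoia_aspera,Calabaria_reinhardtii)))),(Acrochordus_granulatus,(Achalinus_meiguensis,((Azemiops_feae,(Daboia_russelii,(Deinagkistrodon_acutus,((Ovophis_monticola,Ovophis_okinavensis),((Gloydius_brevicaudus,Gloydius_intermedius),((Protobothrops_mucrosquamatus,Protobothrops_flavoviridis),(Trimeresurus_albolabris,(Agkistrodon_piscivorus,Crotalus_horridus)))))))),((Enhydris_plumbea,Homalopsis_buccata),(((Bungarus_fasciatus,Bungarus_multicinctus),((Ophiophagus_hannah,(Naja_atra,Naja_naja)),(Micrurus_fulvius,(Laticauda_colubrina,Hydrophis_cyanocinctus)))),((Ahaetulla_prasina,Boiga_kraepelini),((Imantodes_cenchoa,(Leptodeira_septentrionalis,Sibon_nebulatus)),((Rhabdophis_tigrinus,(Sinonatrix_percarinata,Thermophis_baileyi)),((Lycodon_ruhstrati,(Lycodon_rufozonatum,(Lycodon_semicarinatus,Lycodon_flavozonatum))),((Hierophis_viridiflavus,(Ptyas_dhumnades,(Ptyas_korros,Ptyas_mucosa))),((Coelognathus_radiatus,(Euprepiophis_perlacea,Euprepiophis_mandarinus)),((Elaphe_anomala,(Elaphe_bimaculata,Elaphe_davidi)),(Oocatochus_rufodorsatus,(Orthriophis_taeniurus,Pantherophis_guttatus)))))))))))))))));
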