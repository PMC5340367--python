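species,value
C_amoena,395.2
C_procnemis,280.1
D_busckii,139.9
D_mauritiana,157.9
D_erecta,158.9
D_simulans,159.6
D_kanapiae,165.5
D_teissieri,166.3
D_sechellia,166.7
D_varians,166.7
D_yakuba,170.7
D_santomea,171.5
D_melanogaster,174.5
D_ficusphila,190.8
D_birchii,191.2
D_elegans,192.2
D_pallidosa,194.1
D_atripex,195.9
D_ananassae,196.6
D_tani,199
D_punjabiensis,200.8
D_phaeopleura,202.9
D_bipectinata,204.6
D_malerkotliana,204.9
D_takahashii,207.3
D_parabipectinata,210.8
D_orosa,211.9
D_pseudotakahashii,212.2
D_mimetica,212.7
D_serrata,213.3
D_bunnanda,215.2
D_seguyi,215.2
D_nikananu,216.1
D_tsacasi,217.7
D_lutescens,219.1
D_vulcana,222.7
D_ercepeae,224
D_pseudoananassae_nigrens,224
D_prostipennis,227.4
D_pseudoananassae,228.4
D_eugracilis,228.9
D_paralutea,230.8
D_lacteicornis,242.6
D_auraria,245.1
D_triauraria,245.5
D_quadraria,252.1
D_rufa,255.4
D_mayri,257.5
D_fuyamai,264.1
D_baimaii,278.4
D_orena,280.7
D_lucipennis,291
D_pectinifera,297.4
D_suzukii,342.8
D_pseudoobscura,167.7
D_miranda,175.6
D_tolteca,179
D_ambigua,186.8
D_persimilis,197.1
D_azteca,199.5
D_affinis,200.5
D_barbarae,200.5
D_greeni,201.5
D_jambulina,202.7
D_bifasciata,205.4
D_narragansett,205.9
D_kikkawai,210.2
D_algonquin,211
D_bicornuta,213.7
D_diplacantha,232.8
D_biauraria,237.2
D_hydei,206.8
D_neocordata,212.3
D_emarginata,214.1
D_virilis,325.4
D_nebulosa,187.3
D_sucinea,209.6
D_capricorni,211.8
D_paulistorum,231.8
D_equinoxialis,247.9
H_pictiventris,162.8
S_leonensis,261.8
S_stonei,206.8
S_lebanonensis_lebanonensis,210.3
S_pattersoni,213.2
Z_tuberculatus,197.6
Z_sepsoides,212.8
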