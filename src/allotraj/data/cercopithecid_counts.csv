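tribe,species,n_female,n_male
African Colobini,Colobus_angolensis,4,4
African Colobini,Colobus_guereza,21,18
African Colobini,Colobus_polykomos,9,10
African Colobini,Piliocolobus_badius,49,30
African Colobini,Piliocolobus_bouvieri,1,1
African Colobini,Piliocolobus_ellioti,65,44
African Colobini,Piliocolobus_epieni,1,1
African Colobini,Piliocolobus_foai,12,34
African Colobini,Piliocolobus_gordonorum,4,0
African Colobini,Piliocolobus_kirkii,32,10
African Colobini,Piliocolobus_oustaleti,35,40
African Colobini,Piliocolobus_parmentieri,45,21
African Colobini,Piliocolobus_preussi,31,8
African Colobini,Piliocolobus_rufomitratus,5,1
African Colobini,Piliocolobus_temminckii,11,5
African Colobini,Piliocolobus_tephrosceles,8,17
African Colobini,Piliocolobus_tholloni,38,16
African Colobini,Piliocolobus_waldroni,15,6
African Colobini,Procolobus_verus,20,6
Cercopithecini,Allochrocebus_lhoesti,16,17
Cercopithecini,Allochrocebus_preussi,3,5
Cercopithecini,Allenopithecus_nigroviridis,6,8
Cercopithecini,Chlorocebus_aethiops,11,6
Cercopithecini,Chlorocebus_cynosuros,19,15
Cercopithecini,Chlorocebus_djamdjamensis,8,6
Cercopithecini,Chlorocebus_pygerythrus,51,74
Cercopithecini,Chlorocebus_sabaeus,11,30
Cercopithecini,Chlorocebus_tantalus,17,23
Cercopithecini,Cercopithecus_ascanius,33,37
Cercopithecini,Cercopithecus_campbelli,32,29
Cercopithecini,Cercopithecus_cephus,27,28
Cercopithecini,Cercopithecus_diana,29,32
Cercopithecini,Cercopithecus_erythrogaster,4,5
Cercopithecini,Cercopithecus_erythrotis,4,10
Cercopithecini,Cercopithecus_hamlyni,13,15
Cercopithecini,Cercopithecus_mitis,67,78
Cercopithecini,Cercopithecus_mona,15,19
Cercopithecini,Cercopithecus_neglectus,23,27
Cercopithecini,Cercopithecus_nictitans,23,23
Cercopithecini,Cercopithecus_petaurista,15,25
Cercopithecini,Cercopithecus_pogonias,37,38
Cercopithecini,Cercopithecus_sclateri,5,6
Cercopithecini,Erythrocebus_patas,9,16
Cercopithecini,Miopithecus_ogouensis,16,11
Cercopithecini,Miopithecus_talapoin,2,3
Papionini,Cercocebus_atys,30,23
Papionini,Cercocebus_galeritus,19,27
Papionini,Cercocebus_torquatus,9,14
Papionini,Lophocebus_albigena,23,19
Papionini,Lophocebus_aterrimus,19,21
Papionini,Macaca_arctoides,10,11
Papionini,Macaca_assamensis,12,19
Papionini,Macaca_cyclopis,14,12
Papionini,Macaca_fascicularis,184,281
Papionini,Macaca_fuscata,14,11
Papionini,Macaca_hecki,9,9
Papionini,Macaca_leonina,10,8
Papionini,Macaca_maura,3,5
Papionini,Macaca_mulatta,36,23
Papionini,Macaca_nemestrina,15,18
Papionini,Macaca_nigra,13,13
Papionini,Macaca_ochreata,3,2
Papionini,Macaca_pagensis,2,1
Papionini,Macaca_radiata,9,8
Papionini,Macaca_silenus,4,3
Papionini,Macaca_sinica,6,14
Papionini,Macaca_sylvanus,11,3
Papionini,Macaca_thibetana,3,7
Papionini,Macaca_tonkeana,8,5
Papionini,Mandrillus_leucophaeus,21,15
Papionini,Mandrillus_sphinx,6,9
Papionini,Papio_anubis,54,123
Papionini,Papio_cynocephalus,11,59
Papionini,Papio_kindae,11,11
Papionini,Papio_hamadryas,4,19
Papionini,Papio_papio,1,12
Papionini,Papio_ursinus,8,44
Papionini,Theropithecus_gelada,14,16
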