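taxon_id,name,phylum,shape,length_um,width_um,saprobity_code,feeding_guild
amoeba-proteus,Amoeba proteus,Amoebozoa,,,,b,
amoeba-verrucosa,Amoeba verrucosa,Amoebozoa,,,,,
amoeba-villosa,Amoeba villosa,Amoebozoa,,,,a-b,
hartmannella-limacoides,Hartmannella limacoides,Amoebozoa,,,,,
centropyxis-aculeata,Centropyxis aculeata,Amoebozoa,,,,b,
cocholipodium-bilimbosum,Cocholipodium bilimbosum,Amoebozoa,,,,,
cryptodifflugia-oviformis,Cryptodifflugia oviformis,Amoebozoa,,,,,
difflugia-lobostoma,Difflugia lobostoma,Amoebozoa,,,,a-b,
pelomyxa-gruberi,Pelomyxa gruberi,Amoebozoa,,,,p-i,
quadrulella-symmetrica,Quadrulella symmetrica,Amoebozoa,,,,,
nuclearia-delicatula,Nuclearia delicatula,Choanozoa,,,,,
nuclearia-moebius,Nuclearia moebius,Choanozoa,,,,,
nuclearia-simplex,Nuclearia simplex,Choanozoa,,,,,
pinaciophora-fluviatilis,Pinaciophora fluviatilis,Choanozoa,,,,,
acanthocystis-pectinata,Acanthocystis pectinata,Heliozoa,,,,,
acanthocystis-turfacea,Acanthocystis turfacea,Heliozoa,,,,,
heterophrys-myriapoda,Heterophrys myriapoda,Heliozoa,,,,,
pompholyxophrys-punicea,Pompholyxophrys punicea,Heliozoa,,,,,
cyphoderia-ampulla,Cyphoderia ampulla,Cercozoa,,,,,
euglypha-tuberculata,Euglypha tuberculata,Cercozoa,,,,,
pamphagus-hyalinus,Pamphagus hyalinus,Cercozoa,,,,,
trinema-lineare,Trinema lineare,Cercozoa,,,,,
vampyrella-sp,Vampyrella sp.,Cercozoa,,,,,
dinamoeba-mirabilis,Dinamoeba mirabilis,Myzozoa,,,,,
askenasia-volvox,Askenasia volvox,Ciliophora,,,,b,Al;Ki
bursaria-truncatella,Bursaria truncatella,Ciliophora,,,,a-b,O
bursaridium-schewakoffi,Bursaridium schewakoffi,Ciliophora,,,,,
caenomorpha-lauterborni,Caenomorpha lauterborni,Ciliophora,,,,p-m,Ba;Sb
cinetochilum-margaritaceum,Cinetochilum margaritaceum,Ciliophora,,,,p-i,Ba;Al
colpidium-colpoda,Colpidium colpoda,Ciliophora,,,,p-i,Ba;Fl;Al
cyclidium-heptatrichum,Cyclidium heptatrichum,Ciliophora,,,,b,Ba
didinium-nasutum,Didinium nasutum,Ciliophora,oval,,,a-b,R
dileptus-anser,Dileptus anser,Ciliophora,,,,,
euplotes-muscicola,Euplotes muscicola,Ciliophora,ellipsoid,,,,
glaucoma-scintillans,Glaucoma scintillans,Ciliophora,sphere,,,p-a,Ba
lacrymaria-lagenula,Lacrymaria lagenula,Ciliophora,,,,,
lacrymaria-olor,Lacrymaria olor,Ciliophora,,,,b,R
leegaardiella-sp,Leegaardiella sp.,Ciliophora,,,,,
lohmanniella-oviformis,Lohmanniella oviformis,Ciliophora,,,,,
mesodinium-pulex,Mesodinium pulex,Ciliophora,,,,b,O
mesodinium-rubrum,Mesodinium rubrum,Ciliophora,,,,,
monodinium-balbiani,Monodinium balbiani,Ciliophora,,,,o-a,R
paradileptus-elephantinus,Paradileptus elephantinus,Ciliophora,cone,,,b,O
paramecium-aurelia,Paramecium aurelia,Ciliophora,,,,a-b,Ba
paramecium-bursaria,Paramecium bursaria,Ciliophora,,,,a-b,Ba;Al;Ki
phascolodon-vorticella,Phascolodon vorticella,Ciliophora,,,,a-b,Al;Ki
prorodon-ellipticus,Prorodon ellipticus,Ciliophora,,,,a-b,R
stentor-roeseli,Stentor roeseli,Ciliophora,,,,a-b,O
strobilidium-caudatum,Strobilidium caudatum,Ciliophora,,,,o-b,Ki;Al;Ba
strobilidium-spiralis,Strobilidium spiralis,Ciliophora,cylinder,,,,
strombidium-stylifer,Strombidium stylifer,Ciliophora,,,,,
stylonychia-pustulata,Stylonychia pustulata,Ciliophora,,,,b,O
urotricha-globosa,Urotricha globosa,Ciliophora,,,,a-b,Ba;Al;Fl
vorticella-convallaria,Vorticella convallaria,Ciliophora,,,,a,Ba
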