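# Toy canonical TGF-beta signaling model.
# Ligand/receptor complex formation, Smad2/3 activation, Smad2/3-Smad4
# complex assembly (shared event), importin-dependent nuclear
# translocation, a Smad-only target gene (SMAD7) and a target gene (JUN)
# that is also reachable through a MAPK bypass driven by the receptor
# complex or by EGF.
place EGF;
place IMPORTIN;
place JUN;
place JUN_gene;
place MAPK;
place MAPK_active;
place SMAD2_3;
place SMAD2_3_SMAD4_active_cytoplasm;
place SMAD2_3_SMAD4_active_nucleus;
place SMAD2_3_active;
place SMAD4;
place SMAD7;
place SMAD7_gene;
place TGFB;
place TGFBR;
place TGFB_TGFBR_active;
trans TGFB -[a1 [TGFBR]]-> TGFB_TGFBR_active;
trans TGFBR -[a1 [TGFB]]-> TGFB_TGFBR_active;
trans SMAD2_3 -[a2 [TGFB_TGFBR_active]]-> SMAD2_3_active;
trans SMAD2_3_active -[a3 [SMAD4]]-> SMAD2_3_SMAD4_active_cytoplasm;
trans SMAD4 -[a3 [SMAD2_3_active]]-> SMAD2_3_SMAD4_active_cytoplasm;
trans SMAD2_3_SMAD4_active_cytoplasm -[a4 [IMPORTIN]]-> SMAD2_3_SMAD4_active_nucleus;
trans SMAD7_gene -[a5 [SMAD2_3_SMAD4_active_nucleus]]-> SMAD7;
trans MAPK -[a6 [TGFB_TGFBR_active]]-> MAPK_active;
trans MAPK -[a8 [EGF]]-> MAPK_active;
trans JUN_gene -[a7 [SMAD2_3_SMAD4_active_nucleus or MAPK_active]]-> JUN;
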