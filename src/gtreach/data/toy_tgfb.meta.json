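{
 "comment": "Expected answers for the toy TGF-beta fixture, computed with the explicit-state breadth-first oracle (independent of the SAT path) and frozen here.",
 "frontier": ["EGF", "IMPORTIN", "JUN_gene", "MAPK", "SMAD2_3", "SMAD4", "SMAD7_gene", "TGFB", "TGFBR"],
 "nuclear_complex": "SMAD2_3_SMAD4_active_nucleus",
 "nuclear_complex_step": 4,
 "script_frontier": ["TGFB", "TGFBR", "SMAD2_3", "SMAD4", "IMPORTIN"],
 "script_timing": [["a1"], ["a2"], ["a3"], ["a4"]],
 "smad_only_gene": "SMAD7",
 "bypass_gene": "JUN",
 "stimuli": ["TGFB", "EGF"],
 "anchor": "TGFB",
 "minimal_f_sets": {
  "SMAD7": [
   ["IMPORTIN", "SMAD2_3", "SMAD4", "SMAD7_gene", "TGFB", "TGFBR"]
  ],
  "JUN": [
   ["EGF", "JUN_gene", "MAPK"],
   ["IMPORTIN", "JUN_gene", "SMAD2_3", "SMAD4", "TGFB", "TGFBR"],
   ["JUN_gene", "MAPK", "TGFB", "TGFBR"]
  ]
 },
 "smad_classes": {"SMAD7": "smad-only", "JUN": "mixed"}
}
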