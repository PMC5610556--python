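{
  "key_id": "inglebyi_group",
  "title": "Key to the Indian species of the Tetramorium inglebyi group (workers)",
  "notes": [
    "Tree-shaped key: 4 couplets, 5 species terminals.",
    "Documented numeric gap: couplet 2 does not place intermediate propodeal spine lengths; the gap state is treated as unknown by partial traversal."
  ],
  "characters": [
    {"id": "eye_vs_scape_width", "kind": "categorical",
     "states": ["longer_than_scape_width", "shorter_than_scape_width"],
     "description": "Eye length relative to the maximum width of the antennal scape",
     "figure": "Fig. 13A-E"},
    {"id": "propodeal_spines_relative", "kind": "categorical",
     "states": ["shorter", "intermediate", "longer"],
     "gap_states": ["intermediate"],
     "description": "Relative length of the propodeal spines within the group",
     "figure": "Figs 13F-G, 14E-F"},
    {"id": "petiole_dorsum_proportions", "kind": "categorical",
     "states": ["much_broader_than_long", "as_long_as_broad_or_longer"],
     "description": "Proportions of the petiolar node dorsum in dorsal view",
     "figure": "Fig. 13H-I"},
    {"id": "procoxae_sculpture", "kind": "categorical",
     "states": ["completely_reticulate_punctate", "not_completely_reticulate_punctate"],
     "description": "Sculpture of the procoxae"},
    {"id": "petiole_node_profile", "kind": "categorical",
     "states": ["higher_and_thinner", "thicker_and_compact"],
     "description": "Aspect of the petiolar node in profile",
     "figure": "Fig. 14A-B"},
    {"id": "promesonotum_sculpture", "kind": "categorical",
     "states": ["reticulate_rugose", "longitudinally_rugulose"],
     "description": "Sculpture on the dorsum of the promesonotum",
     "figure": "Fig. 14C-D"},
    {"id": "peduncle_lamella", "kind": "boolean",
     "description": "Peduncle of petiole with a large anteroventral lamella in profile",
     "figure": "Fig. 14E-F"},
    {"id": "petiole_node_shape", "kind": "categorical",
     "states": ["narrowing_apically_dorsum_convex", "square_dorsum_straight"],
     "description": "Shape of the petiolar node in profile",
     "figure": "Fig. 14E-F"}
  ],
  "couplets": [
    {"number": 1, "leads": [
      {"text": "Eyes large, always longer than maximum width of antennal scapes",
       "predicate": {"char": "eye_vs_scape_width", "op": "eq", "value": "longer_than_scape_width"},
       "terminal": "inglebyi"},
      {"text": "Eyes much smaller than above, always shorter than maximum width of antennal scapes",
       "predicate": {"char": "eye_vs_scape_width", "op": "eq", "value": "shorter_than_scape_width"},
       "goto": 2}
    ]},
    {"number": 2, "leads": [
      {"text": "Propodeal spines relatively shorter; dorsum of petiolar node in dorsal view conspicuously much broader than long; procoxae never completely reticulate-punctate",
       "predicate": {"char": "propodeal_spines_relative", "op": "eq", "value": "shorter"},
       "advisory": {"all": [
         {"char": "petiole_dorsum_proportions", "op": "eq", "value": "much_broader_than_long"},
         {"char": "procoxae_sculpture", "op": "eq", "value": "not_completely_reticulate_punctate"}
       ]},
       "goto": 3},
      {"text": "Propodeal spines relatively longer; dorsum of petiolar node in dorsal view about as long as broad or clearly longer than broad; procoxae completely reticulate-punctate",
       "predicate": {"char": "propodeal_spines_relative", "op": "eq", "value": "longer"},
       "advisory": {"all": [
         {"char": "petiole_dorsum_proportions", "op": "eq", "value": "as_long_as_broad_or_longer"},
         {"char": "procoxae_sculpture", "op": "eq", "value": "completely_reticulate_punctate"}
       ]},
       "goto": 4}
    ]},
    {"number": 3, "leads": [
      {"text": "In profile petiolar node appearing higher and thinner; dorsum of promesonotum reticulate-rugose; first gastral tergite unsculptured, smooth and shiny",
       "predicate": {"char": "petiole_node_profile", "op": "eq", "value": "higher_and_thinner"},
       "advisory": {"char": "promesonotum_sculpture", "op": "eq", "value": "reticulate_rugose"},
       "terminal": "elisabethae"},
      {"text": "In profile petiolar node appearing thicker and more compact; dorsum of promesonotum longitudinally rugulose; base of first gastral tergite longitudinally rugulose",
       "predicate": {"char": "petiole_node_profile", "op": "eq", "value": "thicker_and_compact"},
       "advisory": {"char": "promesonotum_sculpture", "op": "eq", "value": "longitudinally_rugulose"},
       "terminal": "triangulatum"}
    ]},
    {"number": 4, "leads": [
      {"text": "Propodeum with comparatively longer spines; in profile peduncle of petiole with large anteroventral lamella; shape of petiolar node narrowing from base to apex and dorsum convex",
       "predicate": {"char": "peduncle_lamella", "op": "eq", "value": true},
       "advisory": {"char": "petiole_node_shape", "op": "eq", "value": "narrowing_apically_dorsum_convex"},
       "terminal": "myops"},
      {"text": "Propodeum with comparatively shorter spines; in profile peduncle of petiole without large anteroventral lamella; shape of petiolar node appearing square and dorsum straight",
       "predicate": {"char": "peduncle_lamella", "op": "eq", "value": false},
       "advisory": {"char": "petiole_node_shape", "op": "eq", "value": "square_dorsum_straight"},
       "terminal": "jarawa"}
    ]}
  ]
}
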