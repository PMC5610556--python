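{
  "key_id": "tonganum_group",
  "title": "Key to the Indian species of the Tetramorium tonganum group (workers)",
  "notes": [
    "Tree-shaped key: 4 couplets, 5 species terminals.",
    "The non-Indian T. tonganum is retained as a terminal because the species is widespread in tropical Asia and future records from India are plausible.",
    "The printed lead labels of the source key run 1-5 but resolve to 4 decision points; the structural encoding uses couplets 1-4 and keeps the printed wording in the lead texts."
  ],
  "characters": [
    {"id": "propodeal_armament", "kind": "categorical",
     "states": ["unarmed", "armed"],
     "description": "Propodeum armed with teeth or spines, or fully unarmed",
     "figure": "Fig. 22A-B"},
    {"id": "petiolar_node_profile", "kind": "categorical",
     "states": ["enlarged_elongated_convex", "not_enlarged"],
     "description": "Petiolar node in profile enlarged, conspicuously elongated and convex, or not",
     "figure": "Fig. 22C-F"},
    {"id": "petiolar_node_proportions", "kind": "categorical",
     "states": ["low_longer_than_high", "higher_than_long"],
     "description": "Petiolar node proportions in profile",
     "figure": "Fig. 22D-F"},
    {"id": "peduncle_shape", "kind": "categorical",
     "states": ["long_and_curved", "short_and_straight"],
     "description": "Shape of the petiolar peduncle in profile",
     "figure": "Fig. 22E-F"}
  ],
  "couplets": [
    {"number": 1, "leads": [
      {"text": "Propodeum unarmed without teeth or spines",
       "predicate": {"char": "propodeal_armament", "op": "eq", "value": "unarmed"},
       "terminal": "krishnani"},
      {"text": "Propodeum armed with teeth or spines",
       "predicate": {"char": "propodeal_armament", "op": "eq", "value": "armed"},
       "goto": 2}
    ]},
    {"number": 2, "leads": [
      {"text": "In profile petiolar node appearing enlarged and conspicuously elongated and convex",
       "predicate": {"char": "petiolar_node_profile", "op": "eq", "value": "enlarged_elongated_convex"},
       "terminal": "barryi"},
      {"text": "In profile petiolar node not appearing enlarged and significantly less elongated and convex",
       "predicate": {"char": "petiolar_node_profile", "op": "eq", "value": "not_enlarged"},
       "goto": 3}
    ]},
    {"number": 3, "leads": [
      {"text": "In profile petiolar node low and appearing longer than high",
       "predicate": {"char": "petiolar_node_proportions", "op": "eq", "value": "low_longer_than_high"},
       "terminal": "christiei"},
      {"text": "In profile petiolar node clearly higher and appearing higher than long",
       "predicate": {"char": "petiolar_node_proportions", "op": "eq", "value": "higher_than_long"},
       "goto": 4}
    ]},
    {"number": 4, "leads": [
      {"text": "In profile peduncle of petiole long and curved",
       "predicate": {"char": "peduncle_shape", "op": "eq", "value": "long_and_curved"},
       "terminal": "tonganum"},
      {"text": "In profile peduncle of petiole short and straight",
       "predicate": {"char": "peduncle_shape", "op": "eq", "value": "short_and_straight"},
       "terminal": "salvatum"}
    ]}
  ]
}
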