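{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/tetrakey/key_schema.json",
  "title": "Dichotomous key file",
  "description": "Published schema of the key JSON format. The loader performs equivalent structural validation internally; this document is the normative description of the interface.",
  "type": "object",
  "required": ["key_id", "characters", "couplets"],
  "properties": {
    "key_id": {"type": "string"},
    "title": {"type": "string"},
    "notes": {"type": "array", "items": {"type": "string"}},
    "characters": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "kind"],
        "properties": {
          "id": {"type": "string"},
          "kind": {"enum": ["categorical", "boolean", "count", "quantitative"]},
          "states": {"type": "array", "items": {"type": "string"}},
          "domain": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2},
          "gap_states": {"type": "array", "items": {"type": "string"}},
          "description": {"type": "string"},
          "figure": {"type": "string"}
        }
      }
    },
    "couplets": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["number", "leads"],
        "properties": {
          "number": {"type": "integer", "minimum": 1},
          "leads": {
            "type": "array",
            "minItems": 2,
            "maxItems": 2,
            "items": {
              "type": "object",
              "required": ["text", "predicate"],
              "properties": {
                "text": {"type": "string"},
                "predicate": {"$ref": "#/$defs/predicate"},
                "advisory": {"$ref": "#/$defs/predicate"},
                "goto": {"type": "integer", "minimum": 1},
                "terminal": {"type": "string"}
              },
              "oneOf": [{"required": ["goto"]}, {"required": ["terminal"]}]
            }
          }
        }
      }
    }
  },
  "$defs": {
    "predicate": {
      "oneOf": [
        {
          "type": "object",
          "required": ["char", "op", "value"],
          "properties": {
            "char": {"type": "string"},
            "op": {"enum": ["eq", "ne", "in", "not_in", "le", "lt", "ge", "gt"]},
            "value": {}
          }
        },
        {
          "type": "object",
          "required": ["all"],
          "properties": {"all": {"type": "array", "items": {"$ref": "#/$defs/predicate"}, "minItems": 1}}
        },
        {
          "type": "object",
          "required": ["any"],
          "description": "Disjunction; all atoms must reference the same character.",
          "properties": {"any": {"type": "array", "items": {"$ref": "#/$defs/predicate"}, "minItems": 1}}
        }
      ]
    }
  }
}
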