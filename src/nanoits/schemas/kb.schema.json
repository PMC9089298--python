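{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.invalid/nanoits/kb.schema.json",
  "title": "nanoits knowledge base",
  "description": "Declarative catalogue of modules, category endpoints with qualitative class bins, and assays with characteristics and applicability rules. YAML files with this shape are accepted; JSON is a YAML subset.",
  "type": "object",
  "required": ["schema_version"],
  "properties": {
    "schema_version": {"type": "string", "pattern": "^1\\."},
    "modules": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"$ref": "#/$defs/identifier"},
          "label": {"type": "string"},
          "product_scope": {
            "type": "array",
            "items": {"enum": ["medical_device", "medicinal_product"]}
          }
        }
      }
    },
    "endpoints": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "module", "kind"],
        "properties": {
          "id": {"$ref": "#/$defs/identifier"},
          "module": {"$ref": "#/$defs/identifier"},
          "label": {"type": "string"},
          "kind": {"enum": ["qualitative", "quantitative"]},
          "unit": {"type": "string"},
          "domain": {"$ref": "#/$defs/interval"},
          "selection_mode": {"enum": ["single_choice", "multi_choice"]},
          "classes": {
            "type": "array",
            "items": {
              "oneOf": [
                {"type": "string"},
                {
                  "type": "object",
                  "required": ["label"],
                  "properties": {
                    "label": {"type": "string"},
                    "lower": {"type": "number"},
                    "upper": {"type": "number"},
                    "lower_inclusive": {"type": "boolean", "default": true},
                    "upper_inclusive": {"type": "boolean", "default": false}
                  }
                }
              ]
            }
          }
        }
      }
    },
    "assays": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "module", "measures", "characteristics"],
        "properties": {
          "id": {"$ref": "#/$defs/identifier"},
          "name": {"type": "string"},
          "module": {"$ref": "#/$defs/identifier"},
          "measures": {
            "type": "array",
            "minItems": 1,
            "items": {"$ref": "#/$defs/identifier"}
          },
          "characteristics": {
            "type": "object",
            "required": ["duration", "cost", "resolution", "expertise"],
            "additionalProperties": {"enum": ["low", "medium", "high"]}
          },
          "applicability": {"$ref": "#/$defs/rule"},
          "user_defined": {"type": "boolean", "default": false}
        }
      }
    },
    "module_selection_rules": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["target", "rule"],
        "properties": {
          "target": {"$ref": "#/$defs/identifier"},
          "rule": {"$ref": "#/$defs/rule"}
        }
      }
    }
  },
  "$defs": {
    "identifier": {"type": "string", "pattern": "^[a-z][a-z0-9_]*$"},
    "interval": {
      "type": "object",
      "required": ["lower", "upper"],
      "properties": {
        "lower": {"type": "number"},
        "upper": {"type": "number"},
        "lower_inclusive": {"type": "boolean", "default": true},
        "upper_inclusive": {"type": "boolean", "default": false}
      }
    },
    "rule": {
      "type": "object",
      "minProperties": 1,
      "maxProperties": 1,
      "properties": {
        "and": {"type": "array", "minItems": 2, "items": {"$ref": "#/$defs/rule"}},
        "or": {"type": "array", "minItems": 2, "items": {"$ref": "#/$defs/rule"}},
        "not": {"$ref": "#/$defs/rule"},
        "atom": {
          "type": "object",
          "required": ["form", "endpoint"],
          "properties": {
            "form": {"enum": ["class_is", "class_in", "range_within"]},
            "endpoint": {"$ref": "#/$defs/identifier"},
            "class": {"type": "string"},
            "classes": {"type": "array", "minItems": 1, "items": {"type": "string"}},
            "lower": {"type": "number"},
            "upper": {"type": "number"}
          }
        }
      }
    }
  }
}
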