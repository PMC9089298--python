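{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.invalid/nanoits/dossier.schema.json",
  "title": "nanoits product dossier",
  "description": "A nano-enabled health product: header, nanomaterial components, asserted classification/characterization classes per scope ('nm' for the whole nanomaterial, otherwise a component name), and raw measurement records.",
  "type": "object",
  "required": ["name", "product_type"],
  "properties": {
    "schema_version": {"type": "string", "pattern": "^1\\."},
    "name": {"type": "string"},
    "description": {"type": "string"},
    "product_type": {"enum": ["medical_device", "medicinal_product"]},
    "md_props": {
      "type": "object",
      "required": ["device_category", "contact_type", "contact_duration"],
      "additionalProperties": {"type": "string"}
    },
    "mp_props": {
      "type": "object",
      "required": ["clinical_indication", "administration_route"],
      "additionalProperties": {"type": "string"}
    },
    "components": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "category", "layers"],
        "properties": {
          "name": {"type": "string"},
          "category": {"enum": ["generic", "api", "excipient", "buffer", "impurity"]},
          "layers": {
            "type": "array",
            "minItems": 1,
            "items": {"enum": ["core", "shell", "coating"]}
          },
          "concentration": {"type": "number"},
          "concentration_unit": {"type": "string"},
          "cas_number": {"type": "string", "pattern": "^\\d{2,7}-\\d{2}-\\d$"}
        }
      }
    },
    "facts": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "properties": {
          "classes": {
            "type": "object",
            "additionalProperties": {
              "oneOf": [
                {"type": "string"},
                {"type": "array", "minItems": 1, "items": {"type": "string"}}
              ]
            }
          },
          "values": {"type": "object", "additionalProperties": {"type": "number"}}
        }
      }
    },
    "measurements": {
      "type": "object",
      "additionalProperties": {
        "type": "array",
        "items": {
          "type": "object",
          "required": ["assay_id", "endpoint_id", "value"],
          "properties": {
            "assay_id": {"type": "string"},
            "endpoint_id": {"type": "string"},
            "value": {"type": "number"},
            "unit": {"type": "string"},
            "conditions": {"type": "string"},
            "media": {"type": "string"},
            "replicate": {"type": "integer", "minimum": 1},
            "timestamp": {"type": "string"}
          }
        }
      }
    },
    "provenance": {"type": "object"}
  }
}
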