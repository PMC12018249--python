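{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "immunoqsp scenario configuration",
  "type": "object",
  "properties": {
    "mode": {"enum": ["invitro_stimulation", "invitro_coculture", "invivo"]},
    "horizon": {"type": "number", "exclusiveMinimum": 0, "description": "days"},
    "n_out": {"type": "integer", "minimum": 2},
    "v0_mm3": {"type": "number", "exclusiveMinimum": 0, "description": "initial tumor volume (in-vivo)"},
    "densities": {
      "type": "object",
      "description": "in-vitro effective contact densities, cells/mm^3",
      "properties": {
        "T": {"type": "number", "minimum": 0},
        "tumor": {"type": "number", "minimum": 0},
        "APC": {"type": "number", "minimum": 0}
      }
    },
    "treatments": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["drug"],
        "properties": {
          "drug": {
            "type": "object",
            "required": ["name", "modality", "arms"],
            "properties": {
              "name": {"type": "string"},
              "modality": {"enum": ["mAb", "BsAb"]},
              "arms": {
                "type": "array", "minItems": 1, "maxItems": 2,
                "items": {
                  "type": "object",
                  "required": ["target", "mode", "kon", "koff"],
                  "properties": {
                    "target": {"type": "string"},
                    "mode": {"enum": ["blocking", "agonist"]},
                    "kon": {"type": "number", "exclusiveMinimum": 0, "description": "1/(nM day)"},
                    "koff": {"type": "number", "exclusiveMinimum": 0, "description": "1/day"}
                  }
                }
              },
              "mw": {"type": "number", "exclusiveMinimum": 0, "description": "g/mol"},
              "alpha": {"type": "number", "exclusiveMinimum": 0, "description": "BsAb trimer crosslink factor"}
            }
          },
          "regimen": {
            "type": ["object", "null"],
            "properties": {
              "dose_mg_per_kg": {"type": "number", "minimum": 0},
              "times": {"type": "array", "items": {"type": "number", "minimum": 0}},
              "route": {"const": "iv_bolus"},
              "body_weight_g": {"type": "number", "exclusiveMinimum": 0}
            }
          },
          "bath_nM": {"type": ["number", "null"], "minimum": 0}
        }
      }
    },
    "registry": {
      "type": "object",
      "description": "parameter overrides: bare numbers (value-only) or full entries",
      "additionalProperties": {
        "oneOf": [
          {"type": "number"},
          {
            "type": "object",
            "required": ["value"],
            "properties": {
              "value": {"type": "number"},
              "units": {"type": "string"},
              "lower": {"type": "number"},
              "upper": {"type": "number"},
              "role": {"enum": ["binding", "signaling", "cell", "pk", "expression"]},
              "source": {"type": "string"}
            }
          }
        ]
      }
    },
    "profiles": {
      "type": "object",
      "description": "checkpoint expression layout per cell type",
      "properties": {
        "profiles": {
          "type": "object",
          "additionalProperties": {
            "type": "object",
            "additionalProperties": {
              "type": "object",
              "required": ["parameter"],
              "properties": {
                "parameter": {"type": "string"},
                "induced": {"type": "boolean"}
              }
            }
          }
        }
      }
    },
    "solver": {
      "type": "object",
      "properties": {
        "rtol": {"type": "number", "exclusiveMinimum": 0},
        "atol": {"type": "number", "exclusiveMinimum": 0},
        "method": {"type": "string"}
      }
    },
    "seed": {"type": "integer"},
    "options": {
      "type": "object",
      "properties": {
        "desensitization": {"type": "boolean"},
        "tgi_convention": {"enum": ["ratio", "delta"]},
        "kill_effector_basis": {"enum": ["ratio", "count"]},
        "assay_endpoint_days": {"type": "number", "exclusiveMinimum": 0},
        "partition_delay": {"type": "number", "minimum": 0}
      }
    }
  }
}
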