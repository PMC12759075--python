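{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "lipdiff compare report",
  "type": "object",
  "required": ["labels", "crosstabs", "overlap"],
  "properties": {
    "labels": {"type": "array", "items": {"type": "string"}, "minItems": 2, "maxItems": 3},
    "crosstabs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["x", "y", "both", "x_only", "y_only", "neither", "n", "fisher_p"],
        "properties": {
          "x": {"type": "string"},
          "y": {"type": "string"},
          "both": {"type": "integer", "minimum": 0},
          "x_only": {"type": "integer", "minimum": 0},
          "y_only": {"type": "integer", "minimum": 0},
          "neither": {"type": "integer", "minimum": 0},
          "n": {"type": "integer", "minimum": 1},
          "fisher_p": {"type": "number", "minimum": 0, "maximum": 1}
        }
      }
    },
    "overlap": {
      "type": "object",
      "required": ["regions", "union"],
      "properties": {
        "regions": {"type": "object", "additionalProperties": {"type": "integer", "minimum": 0}},
        "union": {"type": "integer", "minimum": 0},
        "percent_shared": {"type": ["number", "null"], "minimum": 0, "maximum": 100}
      }
    },
    "enrichment": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["calls", "feature", "ratio", "fisher_p"],
        "properties": {
          "calls": {"type": "string"},
          "feature": {"type": "string"},
          "ratio": {"type": "number", "minimum": 0},
          "fisher_p": {"type": "number", "minimum": 0, "maximum": 1}
        }
      }
    }
  }
}
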