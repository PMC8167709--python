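{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "crowdecg dataset",
  "description": "Single-document form of a coded multi-reader annotation dataset: cases with gold-standard finding sets, reader profiles, and one coded annotation per (reader, case).",
  "type": "object",
  "required": ["cases", "readers", "annotations"],
  "properties": {
    "cases": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["case_id", "difficulty", "gold_findings"],
        "properties": {
          "case_id": {"type": "string"},
          "difficulty": {"enum": ["easy", "medium", "difficult"]},
          "gold_findings": {
            "type": "array",
            "items": {"type": "string"},
            "minItems": 1,
            "uniqueItems": true
          },
          "source_difficulty": {
            "type": ["integer", "null"],
            "minimum": 1,
            "maximum": 5
          }
        }
      }
    },
    "readers": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["reader_id", "experience_category"],
        "properties": {
          "reader_id": {"type": "string"},
          "experience_category": {
            "enum": [
              "senior_student",
              "recent_graduate",
              "resident_other",
              "resident_cardiology"
            ]
          }
        }
      }
    },
    "annotations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["reader_id", "case_id", "findings", "confidence"],
        "properties": {
          "reader_id": {"type": "string"},
          "case_id": {"type": "string"},
          "findings": {
            "type": "array",
            "items": {"type": "string"},
            "minItems": 1,
            "uniqueItems": true
          },
          "confidence": {"type": "integer", "minimum": 1, "maximum": 6},
          "self_difficulty": {"type": ["integer", "null"]},
          "used_intuition": {"type": ["boolean", "null"]}
        }
      }
    }
  }
}
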