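{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "vmodel-events-1.0",
  "title": "Clinical events interchange document",
  "type": "object",
  "additionalProperties": false,
  "required": ["schema_version", "patients"],
  "properties": {
    "schema_version": {"type": "string", "const": "1.0"},
    "patients": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["patient_id", "events"],
        "properties": {
          "patient_id": {"type": "string", "minLength": 1},
          "anchor_date": {
            "type": ["string", "null"],
            "format": "date",
            "description": "Document anchor (e.g. admission or dictation date) used to resolve relative temporal expressions"
          },
          "events": {
            "type": "array",
            "items": {
              "type": "object",
              "additionalProperties": false,
              "required": ["event_id", "text", "semantic_type", "appearance_index"],
              "properties": {
                "event_id": {"type": "string", "minLength": 1},
                "text": {"type": "string"},
                "semantic_type": {
                  "enum": ["Purpose", "Sx", "Dx", "Finding", "Drug", "Op",
                           "Other", "Plan", "Test", "Tx", "Adm", "Death",
                           "Disch", "Visit"]
                },
                "appearance_index": {"type": "integer", "minimum": 0},
                "raw_time": {
                  "type": "string",
                  "description": "Verbatim temporal expression; never a normalised date"
                },
                "causal_links": {
                  "type": "array",
                  "items": {"type": "string"},
                  "description": "Event ids this event is a stated cause of (Problem->Action direction)"
                }
              }
            }
          }
        }
      }
    }
  }
}
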