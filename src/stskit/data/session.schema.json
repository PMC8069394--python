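{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/stskit/session.schema.json",
  "title": "Canonical skeleton session log",
  "description": "Array of timestamped events; each carries the recording time in milliseconds, the in-game score, and 25 joint positions in meters (mediolateral, anteroposterior, vertical). An untracked joint is null.",
  "type": "array",
  "minItems": 1,
  "items": {
    "type": "object",
    "required": ["t_ms", "score", "joints"],
    "properties": {
      "t_ms": {"type": "integer", "minimum": 0},
      "score": {"type": "number"},
      "joints": {
        "type": "array",
        "minItems": 25,
        "maxItems": 25,
        "items": {
          "oneOf": [
            {"type": "null"},
            {
              "type": "array",
              "minItems": 3,
              "maxItems": 3,
              "items": {"type": "number"}
            }
          ]
        }
      }
    },
    "additionalProperties": true
  }
}
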