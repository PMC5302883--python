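{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "pigmentnoise/report/v1",
  "title": "pigmentnoise analysis report",
  "type": "object",
  "required": ["schema_version", "package_version", "seed", "parameters", "stages"],
  "properties": {
    "schema_version": {"type": "integer", "const": 1},
    "package_version": {"type": "string"},
    "seed": {"type": "integer"},
    "parameters": {"type": "object"},
    "stages": {
      "type": "object",
      "additionalProperties": {"type": "object"}
    }
  },
  "additionalProperties": false
}
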