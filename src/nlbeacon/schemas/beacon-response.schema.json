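{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "nlbeacon/beacon-response.schema.json",
  "title": "Beacon-style query response (minimal dialect)",
  "type": "object",
  "required": ["granularityReturned", "exists", "downgraded"],
  "properties": {
    "granularityReturned": {"enum": ["boolean", "count", "record"]},
    "exists": {"type": "boolean"},
    "count": {"type": "integer", "minimum": 0},
    "records": {"type": "array", "items": {"type": "object"}},
    "downgraded": {"type": "boolean"}
  }
}
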