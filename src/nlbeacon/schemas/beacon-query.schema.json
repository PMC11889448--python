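{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "nlbeacon/beacon-query.schema.json",
  "title": "Beacon-style query request (minimal dialect)",
  "type": "object",
  "required": ["collectionScope", "entityType", "requestedGranularity", "filters", "requestParameters"],
  "properties": {
    "collectionScope": {"enum": ["cohort", "dataset"]},
    "collectionId": {"type": ["string", "null"]},
    "entityType": {"enum": ["individuals", "biosamples", "runs", "analyses", "g_variants"]},
    "requestedGranularity": {"enum": ["boolean", "count", "record"]},
    "filters": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string", "pattern": "^[A-Za-z][A-Za-z0-9.]*:[A-Za-z0-9._-]+$"},
          "scope": {"type": ["string", "null"]},
          "label": {"type": ["string", "null"]}
        }
      }
    },
    "requestParameters": {
      "type": "object",
      "properties": {
        "variants": {
          "type": "array",
          "items": {
            "type": "object",
            "properties": {
              "assemblyId": {"type": "string"},
              "referenceName": {"type": ["string", "null"]},
              "start": {"type": ["integer", "null"], "minimum": 0},
              "referenceBases": {"type": ["string", "null"], "pattern": "^[ACGTN]+$"},
              "alternateBases": {"type": ["string", "null"], "pattern": "^[ACGTN]+$"},
              "rsid": {"type": ["string", "null"], "pattern": "^rs[0-9]+$"}
            }
          }
        }
      }
    }
  }
}
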