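{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "nrpairs cluster record file, schema version 1",
  "description": "Either a bare array of records or an object {schema_version, provenance, records}.",
  "type": ["array", "object"],
  "$defs": {
    "record": {
      "type": "object",
      "required": ["organism", "cluster_index"],
      "properties": {
        "organism": {"type": "string"},
        "genome_accession": {"type": "string"},
        "cluster_index": {"type": "integer", "minimum": 1},
        "cluster_type": {"type": "string"},
        "modules": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["NRPSpredictor2", "Stachelhaus", "Minowa"],
            "additionalProperties": false,
            "properties": {
              "NRPSpredictor2": {"type": ["string", "null"]},
              "Stachelhaus": {"type": ["string", "null"]},
              "Minowa": {"type": ["string", "null"]}
            }
          }
        },
        "known_match": {
          "type": ["object", "null"],
          "required": ["compound_name"],
          "properties": {
            "compound_name": {"type": "string"},
            "mibig_id": {"type": "string"},
            "identity_percent": {"type": "number", "minimum": 0, "maximum": 100}
          }
        }
      }
    }
  }
}
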