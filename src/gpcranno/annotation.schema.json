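{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "gpcranno annotation set",
  "type": "object",
  "required": [
    "doc_id", "text_sha256", "pipeline_version", "config_digest",
    "stats", "annotations"
  ],
  "properties": {
    "doc_id": {"type": "string"},
    "text_sha256": {"type": "string", "pattern": "^[0-9a-f]{64}$"},
    "pipeline_version": {"type": "string"},
    "config_digest": {"type": "string", "pattern": "^[0-9a-f]{64}$"},
    "stats": {
      "type": "object",
      "additionalProperties": {"type": "integer", "minimum": 0}
    },
    "annotations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["type", "start", "end", "surface"],
        "properties": {
          "type": {"enum": ["species", "protein", "mutation", "residue"]},
          "start": {"type": "integer", "minimum": 0},
          "end": {"type": "integer", "minimum": 0},
          "surface": {"type": "string"},
          "taxid": {"type": "integer"},
          "dclass": {"enum": ["gene_id", "protein_id", "description"]},
          "candidates": {
            "type": "array",
            "items": {
              "type": "array",
              "prefixItems": [{"type": "string"}, {"type": "number"}]
            }
          },
          "normalized": {"type": ["string", "null"]},
          "resolving_species": {"type": ["integer", "null"]},
          "kind": {"enum": ["mutation", "residue"]},
          "scheme": {"enum": ["sequential", "ballesteros_weinstein", "oliveira"]},
          "article_position": {"type": "integer"},
          "wild_type": {"type": "string", "maxLength": 1},
          "mutant": {"type": "string", "maxLength": 1},
          "silent": {"type": "boolean"},
          "amino_acid": {"type": ["string", "null"], "maxLength": 1},
          "general_label": {"type": "string"},
          "protein": {"type": "string"},
          "sequential_position": {"type": ["integer", "null"]},
          "applied_offset": {"type": "integer"},
          "bw_label": {"type": ["string", "null"]},
          "oliveira_label": {"type": ["string", "null"]},
          "validation": {
            "enum": [
              "validated", "corrected_by_offset",
              "general_number_lookup", "unvalidated"
            ]
          },
          "grounding_distance": {"type": ["integer", "null"]},
          "same_sentence": {"type": ["boolean", "null"]}
        }
      }
    }
  }
}
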