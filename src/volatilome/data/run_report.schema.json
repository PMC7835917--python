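{
  "type": "object",
  "required": ["seed", "timestamp", "stages", "wallclock_s"],
  "properties": {
    "seed": {"type": "integer"},
    "timestamp": {"type": "string"},
    "wallclock_s": {"type": "object"},
    "stages": {
      "type": "object",
      "required": ["simulate", "preprocess", "stats", "classify", "dendro"],
      "properties": {
        "simulate": {
          "type": "object",
          "required": ["enabled"],
          "properties": {
            "enabled": {"type": "boolean"},
            "n_cultures": {"type": "integer"},
            "n_blanks": {"type": "integer"},
            "n_peaks": {"type": "integer"},
            "checksums": {"type": "object"}
          }
        },
        "preprocess": {
          "type": "object",
          "required": ["enabled"],
          "properties": {
            "enabled": {"type": "boolean"},
            "n_peaks_in": {"type": "integer"},
            "removed_by_blank": {"type": "integer"},
            "removed_by_correlation": {"type": "integer"},
            "retained": {"type": "integer"}
          }
        },
        "stats": {
          "type": "object",
          "required": ["enabled"],
          "properties": {
            "enabled": {"type": "boolean"},
            "permanova": {"type": "object"},
            "within_between": {"type": "object"},
            "n_peaks_tested": {"type": "integer"},
            "n_significant_kruskal": {"type": "integer"}
          }
        },
        "classify": {
          "type": "object",
          "required": ["enabled"],
          "properties": {
            "enabled": {"type": "boolean"},
            "candidates": {"type": "integer"},
            "general": {"type": "integer"},
            "species_specific": {"type": "integer"},
            "unclassified_candidates": {"type": "integer"}
          }
        },
        "dendro": {
          "type": "object",
          "required": ["enabled"],
          "properties": {
            "enabled": {"type": "boolean"},
            "rf": {"type": "integer"},
            "normalized_rf": {"type": "number"},
            "cophenetic_r": {"type": "number"}
          }
        }
      }
    }
  }
}
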