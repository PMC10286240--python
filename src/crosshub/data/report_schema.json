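{
  "type": "object",
  "required": [
    "metadata",
    "deg_summary",
    "group_sizes",
    "venn_region_counts",
    "module1",
    "module2",
    "hub_union",
    "enrichment",
    "common_terms",
    "regulators"
  ],
  "properties": {
    "metadata": {
      "type": "object",
      "required": ["package_version", "seed", "config_hash", "thresholds", "skipped_stages"],
      "properties": {
        "package_version": {"type": "string"},
        "seed": {"type": "integer"},
        "config_hash": {"type": "string"},
        "thresholds": {"type": "object"},
        "skipped_stages": {"type": "array"}
      }
    },
    "deg_summary": {"type": "object"},
    "group_sizes": {"type": "object"},
    "venn_region_counts": {"type": "object"},
    "module1": {
      "type": "object",
      "required": ["n_genes", "n_network_vertices", "n_network_edges", "hubs", "support"],
      "properties": {
        "n_genes": {"type": "integer"},
        "n_network_vertices": {"type": "integer"},
        "n_network_edges": {"type": "integer"},
        "hubs": {"type": "array"},
        "support": {"type": "object"}
      }
    },
    "module2": {"type": ["object", "null"]},
    "hub_union": {"type": "array"},
    "enrichment": {"type": "object"},
    "common_terms": {"type": "object"},
    "regulators": {
      "type": "object",
      "required": ["mirna", "tf", "drugs"],
      "properties": {
        "mirna": {"type": ["object", "null"]},
        "tf": {"type": ["object", "null"]},
        "drugs": {"type": ["object", "null"]}
      }
    }
  }
}
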