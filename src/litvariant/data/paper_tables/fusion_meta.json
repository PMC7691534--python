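{
  "description": "Aggregate companion values for fusion_comparison.tsv: unique fusion-pair yields for the full-text literature index and for the COSMIC curated database, restricted to a 507-gene fusion panel.",
  "tool_unique_pairs": 1896,
  "reference_unique_pairs": 297
}
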