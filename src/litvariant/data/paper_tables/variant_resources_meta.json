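{
  "description": "Aggregate companion values for variant_resources.tsv: the number of true-positive references present in the other resources but absent from the first resource is reported only in aggregate, not per row.",
  "references_missing_from_first_resource": 13
}
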