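{
  "type": "object",
  "required": [
    "schema_version",
    "package_version",
    "config",
    "n_input",
    "n_scored",
    "n_excluded",
    "exclusions",
    "subjects",
    "confusion",
    "metrics",
    "roc"
  ],
  "properties": {
    "schema_version": {"type": "string"},
    "package_version": {"type": "string"},
    "config": {
      "type": "object",
      "required": ["threshold", "npiq_mode", "decline_method", "use_mt", "seed"]
    },
    "n_input": {"type": "integer"},
    "n_scored": {"type": "integer"},
    "n_excluded": {"type": "integer"},
    "exclusions": {
      "type": "array",
      "items": {"type": "object", "required": ["subject_id", "reason"]}
    },
    "subjects": {
      "type": "array",
      "items": {"type": "object", "required": ["subject_id"]}
    },
    "confusion": {"type": "object", "required": ["tp", "fp", "tn", "fn"]},
    "metrics": {"type": "object", "required": ["sensitivity", "specificity", "ppv", "npv"]},
    "roc": {
      "type": ["object", "null"],
      "required": ["auc", "auc_ci_95", "method", "fpr", "tpr", "thresholds"]
    },
    "group_comparisons": {"type": "array"},
    "logistic": {"type": ["object", "null"]}
  }
}
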