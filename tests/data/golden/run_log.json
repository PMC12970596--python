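{
  "distance": "euclidean",
  "fc_threshold": 1.0,
  "groups": {
    "CTRL": 3,
    "EXP": 3
  },
  "indices_not_evaluated": [],
  "n_lipids": 30,
  "n_skipped": 0,
  "p_threshold": 0.05,
  "scaling": "autoscale",
  "seed": 0,
  "version": "0.1.0"
}
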