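{
  "schema_version": 1,
  "organ": "bladder",
  "a": 1.0,
  "intercept_gy": "45.37",
  "slope_gy_per_cm": "-5.78",
  "n": 60,
  "r2": "0.79",
  "source": "published"
}
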