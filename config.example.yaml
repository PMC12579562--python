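# Example pipeline configuration for `dualkidney run`.
# Omitted keys fall back to package defaults (demo-scale registry,
# ratios 1/2/3 with threshold 0.1, 11-year microsimulation).
registry:
  n_dual: 300
  n_single: 30000
  seed: 11
matching:
  ratios: [1, 2, 3]
  threshold: 0.1
  seed: 12
survival:
  query_years: [1, 2, 4, 6]
projection:
  horizon_years: 5.0
  use_reference_inputs: true
microsim:
  n_candidates: 20000
  seed: 13
  schedule:
    seed: 14
    base_p_transplant: 0.15
    base_p_death: 0.05
    dual_fraction: 0.01
    n_years: 11
    jitter: 0.0
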