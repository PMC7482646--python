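# Demo pipeline configuration: simulated cohort with one enriched gene
# and one spiked diagnostic variant.
seed: 42
simulate:
  n_cases: 120
  n_controls: 120
  enrichment:
    PEX2: 5.0
  spikes:
    - gene: ACAN
      consequence: nonsense
      known_mutation: true
qc:
  ld_r2_max: 0.5
burden:
  alpha: 0.05
  method_all: bonferroni
  method_rare: benjamini_hochberg
association:
  alpha: 0.05
  lenient: 0.001
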