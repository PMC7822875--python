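# Two-chromosome demo: simulate, impute, estimate heritability, scan,
# threshold, LD interval, founder effects, and mediation in one run.
out_dir: scratch/demo_run
seed: 1
simulate:
  n_animals: 150
  chromosomes:
    - ["1", 50.0, 60]
    - ["2", 50.0, 60]
  n_founders: 8
  n_generations: 25
  genotyping_error: 0.002
  missing_rate: 0.01
  h2: 0.35
  qtl:
    marker_index: 30
    effects: snp   # founder allele pattern at the marker (SNP-taggable QTL)
    fraction: 0.25
  expression_scenario: full_mediation
hmm:
  generations: 25
  epsilon: 0.005
scan:
  B: 60
  alpha: 0.05
  r2_min: 0.5
h2:
  n_iter: 5000
  burn_in: 500
effects:
  n_importance: 10
  n_iter: 400
  burn_in: 100
mediation:
  fdr: 0.1
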