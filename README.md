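# hsqtl

QTL mapping toolkit for multiparental (heterogeneous stock) populations.

An HS animal's genome is a mosaic of segments inherited from a small set of
inbred founder strains. `hsqtl` implements the full mapping chain for such
populations:

- **`hsqtl.hmm`** — founder-diplotype inference along the genome: a hidden
  Markov model over the F(F+1)/2 unordered founder pairs (36 states for 8
  founders, 28 heterozygous), with a jump-process transition family
  (rate = generations per Morgan, exchangeable founders, Haldane map),
  per-allele genotyping-error emissions, and scaled forward–backward
  recursions. Produces expected founder doses and imputed SNP doses.
- **`hsqtl.lmm`** — kinship from founder dosages and maximum-likelihood
  linear mixed models via a single eigendecomposition plus 1-D profile
  optimization of the variance ratio (REML optional).
- **`hsqtl.scan`** — SNP-by-SNP likelihood-ratio genome scans (logP scale,
  exact per-marker variance refit), genome-wide significance thresholds from
  parametric bootstrap of the fitted null model, and contiguous r² ≥ 0.5 LD
  support intervals around peaks.
- **`hsqtl.heritability`** — Bayesian narrow-sense heritability
  h² = τ²/(τ² + σ²) with Gamma(1,1) priors on both precisions (the induced
  prior on h² is exactly Uniform(0,1)), sampled by a partially collapsed
  Gibbs sampler in the kinship eigenbasis; reported as posterior mode +
  shortest 95% HPD interval.
- **`hsqtl.diploffect`** — founder haplotype-effect and QTL effect-size
  estimation at a peak under diplotype uncertainty: importance sampling over
  diplotype configurations drawn from the HMM posteriors, Laplace-weighted
  by marginal likelihood, each fitted by Gibbs with additive effects per
  founder dose, dominance deviations over the 28 heterozygous states, and a
  polygenic term.
- **`hsqtl.mediation`** — the four-criterion procedure for deciding whether
  a local gene's expression mediates a detected QTL (locality, >25%
  nonzero-expression filter, cis-eQTL with BH FDR 0.1, conditioned
  full-mediation test at p > 0.05, partial-mediation LRT at q ≤ 0.1).
- **`hsqtl.prep`** — rank-based inverse normal transform (Blom offset,
  average-rank ties) and counts-per-million normalization.
- **`hsqtl.simulate`** — a synthetic HS-population generator with known
  ground truth (ancestry mosaics from a Markov jump process, informative
  founder panels, array genotypes with error/missingness, phenotypes with
  controlled polygenic/QTL variance fractions, and expression traits for
  full/partial/no-mediation scenarios), so every stage is verifiable by
  parameter recovery without external data.
- **`hsqtl.io` / `hsqtl.cli` / `hsqtl.pipeline`** — documented TSV formats
  (missing token `NA`), a GT-only VCF importer, schema-validated YAML
  configs with a single master seed, and a `hsqtl` command-line interface.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the long-running calibration and
parameter-recovery criteria (null scan calibration at a bootstrap threshold,
power at a 20%-variance QTL with n = 245, heritability and founder-effect
recovery, end-to-end mediation); the rest of the suite is fast.

## Command line

Every stage is a subcommand (`simulate`, `impute`, `prep`, `h2`, `scan`,
`threshold`, `intervals`, `effects`, `mediate`); `pipeline` runs the whole
chain from a config file and writes a `provenance.json` (versions, config,
per-stage seeds, output hashes) sufficient to reproduce the run exactly:

```sh
hsqtl pipeline --config examples/demo.yaml
```

The demo simulates a 2-chromosome population with a SNP-taggable QTL and a
full-mediation expression scenario, imputes diplotypes, estimates h², scans,
bootstraps a genome-wide threshold, derives the LD interval, estimates
founder effects, and runs mediation — in a few seconds on one CPU.
Usage errors exit 2; data errors exit 1 with a categorized message.

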