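# msrs

Scoring, reliability and factor-structure analysis for multi-rater ordinal
surveys of primate social responsiveness.

The package implements the full validation workflow for a 36-item,
observer-rated survey answered on a 1–4 ordinal scale:

- **`msrs.core_io`** — domain types (questionnaire with reverse-key flags,
  long/wide survey tables, demographics) and CSV/TSV/XLSX readers and
  writers. Skipped answers stay missing; nothing is imputed at load time.
- **`msrs.scoring`** — reverse-keyed 0–3 item scoring (totals range 0–108
  for a complete survey), per-monkey score aggregation, and distribution
  analysis: mean/SD/skewness, a seeded Monte-Carlo Lilliefors normality
  test, and a strictly-greater-than `mean + k·sd` outlier rule.
- **`msrs.reliability`** — two-way mixed, average-measures intraclass
  correlations (consistency `C-k` and absolute-agreement `A-k` variants)
  computed pairwise over raters sharing monkeys, plus per-item Cronbach's
  alpha over a fully-crossed rater block with zero-variance flagging and
  the positive-alpha retention rule.
- **`msrs.factor`** — exploratory factor analysis: correlation-matrix
  eigenvalues, bootstrap lower-CI-above-1 factor retention,
  maximum-likelihood extraction (profile likelihood over uniquenesses,
  matching R's `factanal`), varimax rotation, and bootstrap median
  loadings with percentile CIs. Bootstrap replicates are aligned to the
  full-sample solution by greedy Tucker-congruence matching with sign
  flips before summarizing.
- **`msrs.association`** — Spearman rank correlation (midrank ties, exact
  permutation p for small n) and rank/sex group summaries.
- **`msrs.synth`** — a latent-factor simulator for multi-rater ordinal
  data with known ground truth: sparse rater coverage, a fully-crossed
  rater block, reverse-keyed items, zero-variance items, anti-correlated
  "unreliable" items, rater noise, skipped answers, demographic effects
  and a high-scoring contaminant subpopulation. `paperlike_preset()`
  returns the canonical configuration (105 monkeys × 15 raters across 175
  surveys plus a 16-monkey × 4-rater block; items partitioned 17
  reliable / 14 unreliable / 5 zero-variance).
- **`msrs.pipeline`** — one-call end-to-end run (score → distribution →
  pairwise ICC → item filter → eigenvalue retention → EFA + bootstrap →
  association) with a JSON report, a Markdown summary, and a single seed
  driving per-stage substreams so reruns are byte-identical.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: scoring bounds,
pair-count combinatorics, parameter recovery on the synthetic preset,
oracle equivalence against independent brute-force computations (and
pingouin / R-`factanal`-frozen references), Lilliefors type-I calibration,
and noiseless-limit identities.

## CLI

```sh
msrs simulate --preset paperlike --seed 7 --out sim/
msrs score --input sim/survey.csv --missing-policy prorate --out summary.json
msrs reliability --input sim/survey.csv --block-raters 16,17,18,19 --out rel.json
msrs efa --input sim/survey.csv --items retained.json --n-boot 10000 --seed 1 --out efa.json
msrs assoc --input sim/survey.csv --demographics sim/demographics.csv --out assoc.json
msrs pipeline --survey sim/survey.csv --demographics sim/demographics.csv \
    --config cfg.yaml --out report/
```

The pipeline config is YAML with the fields of
`msrs.pipeline.PipelineConfig` (aggregation, missing policy, ICC variant,
block raters, bootstrap sizes, seed, …).

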