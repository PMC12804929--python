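# complexpqtl

Detect non-linear covariate effects, genetic dominance, and epistasis that
influence quantitative molecular traits (e.g., plasma protein levels) by
comparing a flexible non-linear genomic predictor against a penalized linear
baseline, then decomposing any performance gap with targeted statistical
analyses.

## What is in the box

| Module | Role |
| --- | --- |
| `complexpqtl.simdata` | Synthetic cohorts: Hardy-Weinberg genotypes with optional LD blocks and missingness, covariate tables, and traits with planted additive / dominance / epistatic / GxE / ExE / non-linear-covariate components plus a ground-truth variance ledger |
| `complexpqtl.genio` | PLINK1 `.bed/.bim/.fam` codec (bit-exact, SNP-major), HWE exact test, ordered QC filtering with a reconciling ledger, windowed LD pruning, rank-based inverse normal transform |
| `complexpqtl.assoc` | Additive per-variant OLS scan, p-value pre-filtering, per-genotype non-additivity tests with a dominance contrast, pairwise epistasis scan with Bonferroni bookkeeping |
| `complexpqtl.predictors` | Genotype encodings, cross-validated elastic-net ensemble, locally-connected-then-dense network (numpy, CPU) with integrated-gradients attribution, attribution-ranked variant selection, Bayesian optimization over the retained-variant fraction, interaction-constrained gradient boosting |
| `complexpqtl.pipeline` | Per-trait orchestration: splits, train-only GWAS pre-filter, multi-run training with attribution-guided BO, test-set ensembling, elastic-net benchmark, leakage instrumentation |
| `complexpqtl.gapstats` | Paired bootstrap model comparison, BH FDR, gap-source classification, iterative complexity ladder, staged boosted decomposition, group-wise transfer gaps, Clopper-Pearson intervals |

## CLI

```bash
complexpqtl simulate --out-dir study/ --n-samples 2000 --n-variants 200 --seed 1
complexpqtl qc --prefix study/study --out-prefix study/qc
complexpqtl gwas --prefix study/study --out study/gwas.tsv
complexpqtl train --prefix study/study --out-dir study/run/        # per-trait pipeline
complexpqtl evaluate --predictions study/run/predictions.tsv --out study/summary.json
complexpqtl interactions --prefix study/study --out study/hits.tsv
complexpqtl complexity --prefix study/study --out study/ladder.tsv
```

`--config config.yaml` overrides defaults (`prefilter_p: 1e-3`, `n_runs: 10`,
`n_boot: 1000`, `top_k: 128`, `en_alphas`, `n_lambda: 200`,
`bonferroni_alpha: 0.05`).

## Notes

- Genotype dosage counts copies of allele1 (the effect/minor allele in
  simulated data); missing calls use the sentinel -1 and are never silently
  imputed at the I/O layer.
- The non-linear predictor is a locally connected network implemented in
  numpy with manual backpropagation (no GPU/framework dependency), with a
  proximal L1 penalty on the first-layer weights so sparse genetic signals
  are handled gracefully; gradients w.r.t. inputs power integrated-gradients
  attributions.
- The staged decomposition uses scikit-learn's histogram gradient boosting
  with feature-interaction constraints to isolate GxG and GxE contributions.
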