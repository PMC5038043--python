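# plaque-signals

Statistical pipeline for separating **gingivitis-associated** from
**periodontitis-associated** signals in supragingival-plaque 16S taxon
count data, plus a calibrated synthetic-cohort generator so the whole
analysis can be exercised and validated without any external data.

Periodontal disease spans reversible gum inflammation (gingivitis,
quantified here by the number of dental-arch sextants with bleeding on
probing, BoP 0–6) and irreversible loss of tooth-supporting tissue
(periodontitis, a binary classification). Because the two are strongly
correlated in any natural cohort, attributing a taxon's abundance shift
to one or the other requires modeling them jointly across the full
range of severities. This package implements that analysis for
taxon-by-sample read-count tables:

- **Diversity** — per-sample species richness and Shannon index (nats),
  averaged over repeated rarefactions to a common depth (default 5,000
  reads × 100 iterations), with backward-stepwise AIC linear modeling
  of diversity against clinical covariates
  (AIC = *n* ln(RSS/*n*) + 2*k*).
- **Differential abundance** — per-taxon negative-binomial GLMs with
  log link: counts *y*<sub>ij</sub> ~ NB(μ<sub>ij</sub>, α<sub>i</sub>)
  with Var = μ + αμ², ln μ<sub>ij</sub> = ln *s*<sub>j</sub> +
  β₀ + β₁·BoP<sub>j</sub> + β₂·perio<sub>j</sub> + adjustment terms
  (site, intervention arm, HIV status, sequencing run), where
  *s*<sub>j</sub> is a median-of-ratios size factor. Coefficients via
  IRLS, dispersion by profile maximum likelihood, Wald tests with
  Benjamini–Hochberg correction across taxa, and an intersection report
  of taxa associated with periodontitis but not gingivitis.
- **Cooccurrence networks** — SparCC-style compositional correlation
  inference (log-ratio variation matrix → basis variances → basis
  correlations, with Dirichlet(counts + 1) resampling, iterative
  strong-pair exclusion, and componentwise median aggregation),
  within-taxon permutation pseudo *p*-values, strong-edge thresholds at
  mean + 1.96 SD of off-diagonal correlations, betweenness-centrality
  ranking, and complete-linkage clustering of per-stratum correlation
  matrices on Mantel distances (1 − Pearson *r* of upper triangles).
- **Phylotype selection** — Needleman–Wunsch global percent identity
  (match +1, mismatch −1, gap −2) against a reference set with a strict
  >98.5% cutoff, the species-level threshold used for oral taxa.
- **Community summaries** — Bray–Curtis dissimilarities, principal
  coordinates analysis, stratum-wise summed relative abundances with
  Kruskal–Wallis tests, and cohort descriptive statistics.
- **Synthetic cohorts** — metadata drawn from the printed stratum
  marginals of a 962-woman reference cohort, lognormal library sizes
  moment-matched to 13,565 ± 6,833 reads, NB counts around a log-linear
  mean with optional stratum-specific latent cooccurrence modules, and
  ground truth (effect sizes, basis correlations, module memberships)
  for recovery tests.

## Worked example

```python
import numpy as np, pandas as pd
from plaque_signals.synthetic import GeneratorConfig, LatentModule, generate_cohort
from plaque_signals.community_summary import cohort_summary
from plaque_signals.differential_abundance import run_differential_abundance

taxa = [f"otu{i:04d}" for i in range(100)]
effects = pd.DataFrame({"beta_bop": [np.log(1.45)]}, index=["otu0000"])
cfg = GeneratorConfig(
    n_samples=400, n_taxa=100, effect_table=effects,
    module_spec=[LatentModule(taxa[10:16], loading=1.2, active_periodontitis=True)],
)
counts, meta, truth = generate_cohort(cfg, seed=42)

s = cohort_summary(meta)
print(f"cohort: n={s['n']}, gingivitis {s['gingivitis_pct']:.1f}%, "
      f"periodontitis {s['periodontitis_pct']:.1f}%")

res = run_differential_abundance(counts, meta, pseudo_reference=True)
row = res["tables"]["bop"].loc["otu0000"]
print(f"otu0000 fold change per BoP unit: {row['fold_change']:.2f}")
print("periodontitis-only hits:", res["intersection"]["periodontitis_only"])
```

prints

```
cohort: n=400, gingivitis 85.5%, periodontitis 35.0%
otu0000 fold change per BoP unit: 1.42
periodontitis-only hits: ['otu0010', 'otu0012', 'otu0013', 'otu0014', 'otu0015', 'otu0070']
```

The cohort marginals mirror the reference cohort's prevalences; the
planted 1.45-fold-per-BoP-unit effect on `otu0000` is recovered at 1.42
with a covering 95% CI (1.36–1.48); and the latent module planted in
the periodontitis stratum (`otu0010`–`otu0015`) surfaces in the
periodontitis-but-not-gingivitis intersection.

The same analysis is available from the shell:

```bash
plaque-signals synth --n-samples 400 --n-taxa 100 --seed 42 --outdir demo
plaque-signals diffabund demo/counts.tsv demo/metadata.tsv --outdir demo
plaque-signals run config.yaml     # full pipeline from a YAML config
```

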