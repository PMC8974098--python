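# depth2

Reference-free scoring of intratumor heterogeneity (ITH) from bulk
gene-expression profiles, for cancer genomics analysts working with
cohorts (RNA-seq or microarray) that lack matched normal controls.

## The score

Given a normalized expression matrix with *m* genes and *t* tumor
samples, each gene *i* is absolute-z-scored against the cohort itself:

```
absz(i, j) = | ex(Gi, Tj) − mean_i | / SD_i
```

with `mean_i` and `SD_i` (sample SD, t−1 denominator) taken across the
*t* samples. The ITH score of sample *j* is the standard deviation
(m−1 denominator) of its column of absolute z-scores:

```
DEPTH2(Tj) = SD_i [ absz(i, j) ]
```

A transcriptome whose genes all sit at similar normalized distances from
the cohort centre is "synchronous" and scores low; asynchronous
alteration levels across genes — the bulk signature of a mixture of
transcriptionally distinct tumor-cell subclones — score high. Because
the cohort provides the per-gene location and scale, no normal reference
is needed, but scores are cohort-dependent by construction.

Around the score, the package bundles the standard analysis battery:
log2(x+1) preprocessing, tumor-purity adjustment (score / purity),
tumor-mutation-burden counting from MAF tables, ssGSEA signature
scoring and two-signature log-ratios, Spearman correlation screens with
Benjamini–Hochberg FDR, one-sided Mann–Whitney U and Kruskal–Wallis
comparisons, and median-split Kaplan–Meier / log-rank survival analysis
— plus a clone-mixture simulator that generates bulk cohorts with known
clone counts, purities and noise so the whole pipeline can be validated
without any external data.

## Worked example

```python
from depth2 import (SimulationConfig, simulate_cohort, score_expression,
                    truth_join, median_split, km_logrank, simulate_survival,
                    mannwhitney_one_sided)

cfg = SimulationConfig(n_genes=500, n_tumors=100, n_normals=50, seed=7)
cohort = simulate_cohort(cfg)                      # bulk mixtures of 1..8 clones
scores = score_expression(cohort.matrix, already_log2=True)
joined = truth_join(cohort, scores)
print(joined[~joined.is_normal].groupby("k")["depth2"].mean().round(3))
```

```
k
1    0.638
2    0.728
3    0.801
4    0.802
5    0.873
6    0.861
7    0.925
8    1.003
```

Mean score rises with the true clone count: tumors built from more
transcriptionally distinct subclones carry more asynchronous expression
alterations. Normals (pure baseline + noise) score far lower, and a
median split on the score separates survival when the simulated hazard
grows with clone count:

```python
tum = joined.loc[~joined.is_normal.astype(bool), "depth2"]
nor = joined.loc[joined.is_normal.astype(bool), "depth2"]
res = mannwhitney_one_sided(tum, nor, "greater")
# tumor mean 0.816 vs normal mean 0.308, MW p = 1.09e-23

surv = simulate_survival(cohort.truth, seed=8)     # hazard increases with k
comp = km_logrank(surv, median_split(scores), endpoint="os")
# median-split log-rank chi2 = 13.73, p = 0.000211
```

## Command line

```sh
depth2 score --expr matrix.tsv --out scores.tsv            # log2(x+1) applied
depth2 score --expr matrix.tsv --already-log2 \
             --cohort clinical.tsv --out scores.tsv        # + purity adjustment
depth2 ssgsea --expr matrix.tsv --gmt sets.gmt --out enrich.tsv
depth2 ratio --expr matrix.tsv --set-a CD8.txt --set-b Treg.txt --out ratio.tsv
depth2 correlate --scores scores.tsv --cohort clinical.tsv \
                 --vars tmb,cna,hrd,purity --family per-cohort --out corr.tsv
depth2 compare --scores scores.tsv --cohort clinical.tsv \
               --group stage_group --positive-class late --alternative greater
depth2 survive --scores scores.tsv --cohort clinical.tsv --endpoint os --out km.tsv
depth2 simulate --config sim.yaml --out-prefix sim
depth2 pipeline --config pipe.yaml --out-dir run/       # stages + manifest.json
```

All tables are TSV (`.csv` switches the delimiter); expression matrices
have genes as rows with a `gene_id` first column. Each pipeline run
writes a `manifest.json` recording the command, config, input digests,
seed, package version and warnings, and reruns with the same config and
seed are byte-identical.

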