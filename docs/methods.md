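# Methods

## The ITH statistic

For an expression matrix of *m* genes × *t* tumor samples, gene *i* in
sample *j* gets an absolute z-score
`absz(i,j) = |x_ij − mean_i| / SD_i`, with `mean_i` and `SD_i` computed
over the *t* samples and `SD_i` using the t−1 denominator. The DEPTH2
score of sample *j* is the standard deviation (m−1 denominator) of
`absz(·, j)`. Both denominators follow the defining formula exactly.

Properties that follow directly, and that the test suite asserts:

- **Non-negativity** — an SD of non-negative quantities.
- **Gene-wise affine invariance** — z-scoring removes each gene's
  location and scale, so `x_i → a + b·x_i` (b > 0) never changes a score.
- **Degenerate t = 2** — with two samples every non-constant gene has
  `absz = 1/√2` in both, so all scores are exactly 0; cohorts of two
  cannot carry heterogeneity information under this statistic.
- **Cohort dependence** — per-gene statistics come from the supplied
  matrix, so adding/removing samples changes the remaining scores.
  Scores are comparable within a cohort, not across cohorts.

Numerical choices: genes with `SD_i ≤ 1e-12` on the working scale are
dropped (a constant gene has undefined z and no heterogeneity signal)
and recorded in `AbsZMatrix.dropped_genes`; scoring requires at least
two retained genes; a matrix whose genes are all constant is a hard
error ("no informative genes").

**Preprocessing.** RNA-seq style inputs are transformed `v → log2(v+1)`
before scoring; already-log-scaled data (e.g. microarray intensities)
skip the transform via the `log2p1` scale flag / `--already-log2`.

**Reference population.** By default every supplied sample enters the
per-gene statistics (so normals, if present, are z-scored within the
pooled matrix). `absolute_zscore(..., ref_samples=...)` instead
freezes the per-gene means/SDs to a designated subset (e.g. tumors
only) while scoring all columns. Both modes are exposed because
either convention is defensible when scoring normal controls; the
default is the pooled matrix.

**Purity adjustment.** Bulk scores rise with tumor-cell content, since
the normal admixture pulls every sample toward a shared profile. The
adjusted score is `depth2 / purity`, with purity a fraction in (0, 1]
(pathology-slide tumor-cell proportion or an expression-based estimate
— the caller maps whichever column is appropriate; the two are not
interchangeable and the tool does not conflate them). Samples without
purity keep a missing adjusted score.

**TMB.** Tumor mutation burden is the raw count of somatic mutation
records per sample in the supplied MAF-style table; samples absent
from the table count 0.

## ssGSEA variant

Per sample, genes are ranked by expression (ascending average ranks, so
the top gene of N has rank N; ordering ties broken by gene id for
order-independence). Walking genes in descending-expression order, the
enrichment score is the summed difference between the weighted in-set
cumulative distribution — rank weights raised to the exponent `weight`,
normalized to sum 1 within the set — and the uniform out-of-set
cumulative distribution. Defaults: `weight = 0.25` (common ssGSEA
practice), `min_overlap = 2` genes between set and matrix, no
cross-sample normalization (a `normalize="range"` option divides the
whole table by its cohort-wide ES range for users matching other
toolchains). `weight = 0` reduces to the plain two-ECDF (KS-like)
difference. Only ranks enter, so any monotone transform of the input
leaves scores unchanged.

The **signature ratio** of sets A over B is the per-sample arithmetic
mean of log2 values over A minus that over B — the log2 ratio of
geometric means of the (pseudocounted) linear values. For linear
input, `pseudocount=False` uses log2(v) instead of log2(v+1) and makes
the ratio invariant to global rescaling; the log-scale/pseudocount form
is the default.

## Statistical battery

- **Median split**: strictly above the median → "high", strictly below
  → "low"; ties at the median are excluded and counted. Requires ≥ 4
  samples and non-constant scores.
- **Spearman screens**: pairwise-complete observations, t-approximation
  p-values, BH FDR within a caller-declared family (the family is an
  explicit argument because which tests share one correction is an
  analysis decision, not a property of the data). Pairs with n < 3 or a
  constant column are reported as undefined and excluded from the family.
- **Mann–Whitney U** (one-sided, direction always explicit): exact null
  distribution when the combined n ≤ 20 with no ties, otherwise the
  normal approximation with tie and continuity corrections.
- **Kruskal–Wallis** for ≥ 3 groups, tie-corrected H against χ²(k−1);
  an all-identical input returns H = 0, p = 1 by convention.
- **Survival**: Kaplan–Meier product-limit curves per group and the
  unweighted (Mantel–Haenszel) two-group log-rank test, delegated to
  lifelines. An optional stratified variant sums the per-stratum O−E
  and variance terms before forming the 1-df chi-square; it is off by
  default, and pooled analyses concatenate cohorts unstratified. A
  group with zero events warns but is still tested.

## The simulator

`simulate_cohort` emulates a bulk cohort in which heterogeneity is the
manipulated variable. On the log2(x+1) scale:

- a baseline (normal) profile is drawn once, gene-wise
  N(mean = 8, SD = 2), clipped at 0 — a spread typical of log-scale
  normalized expression;
- each tumor has k clones forming a **linear genealogy**: clone 1 is
  the baseline plus an independent N(0, δ²) perturbation on a random
  fraction f of genes, and each subsequent clone inherits its parent's
  alterations and adds its own on a fresh random subset. Ancestral
  alterations are carried by every clone (fully clonal) while recent
  ones are private (subclonal), so the bulk mixture contains
  alterations at a spectrum of cellular fractions — the asynchronous
  pattern the score detects. A flat mixture of mutually independent
  clones would instead average alterations away (bulk perturbation
  variance shrinking like 1/k) and invert the score–clone-count
  relationship;
- clone weights are symmetric Dirichlet(α = 1) (or equal with
  `clone_mixing="uniform"`); bulk signal =
  purity · (weighted clone mixture) + (1 − purity) · baseline;
- i.i.d. N(0, σ²) noise is added per gene and values are clipped at 0;
  the clip rate is recorded and stays well under 5% at the defaults;
- normals are baseline + noise only, isolating heterogeneity (not
  tissue identity) as the difference between groups.

Defaults: 500 genes, 100 tumors, 50 normals, k uniform on {1..8},
f = 0.2, δ = 1.0 log2 units (a typical strong expression alteration),
σ = 0.3 log2 units of measurement noise, purity fixed at 1. All
randomness flows from one integer seed; identical configs are
bit-identical. `simulate_survival` attaches exponential survival times
with hazard `λ0 · exp(0.35·(k−1))`, λ0 = ln2/1000 per day (single-clone
median ≈ 1000 days), administratively censored at 2000 days.

What the simulator does **not** emulate: realistic gene–gene
correlation structure, platform/batch effects, count-level sampling
noise, copy-number-driven expression dosage, or tissue-specific normal
profiles. Passing tests therefore demonstrate the internal consistency
and directional behaviour of the method under a controlled generative
model, not its accuracy on any particular real cohort.

## Validation design and problem sizes

Every operation with a closed-form or enumerable oracle is tested
against an independent naive implementation: the scorer against a
triple-loop transcription of the defining formula (50 random matrices,
5–100 genes × 3–50 samples, relative error ≤ 1e-10), ssGSEA against a
stepwise running-sum oracle, the exact Mann–Whitney branch against full
enumeration of all label assignments at combined n ≤ 8, BH against the
step-up rule, KM (uncensored) against the empirical survival function,
and the log-rank test against hand-accumulated 2×2 tables plus a
1000-replicate null calibration at α = 0.05 (rejection rate within 3
binomial SDs). Simulation-based checks use cohorts of 50–200 tumors
and 500 genes — large enough for stable directional effects, small
enough that the full suite and the acceptance script each run in about
half a minute on one CPU. `scripts/acceptance.py` recomputes all of
these quantities from a single command-line seed.

## Known limitations

- Scores are not calibrated across cohorts or platforms; large
  inter-gene scale differences across technologies can dominate the
  z-scores (min–max or rank normalization upstream may help and is out
  of scope here).
- Bulk scores confound tumor-cell heterogeneity with purity; the
  division-by-purity adjustment is crude and can over-correct (the
  adjusted score's purity correlation typically swings negative in
  simulation while shrinking in magnitude).
- Two-sample cohorts are uninformative (all scores 0), and very small
  cohorts give noisy per-gene SDs.
- The GMT/MAF/clinical readers cover the plain-text dialects only; no
  HDF5/MTX/loom containers, no accession downloading, no Excel.
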