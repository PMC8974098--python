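"""The DEPTH2 scoring core.

Given a normalized gene expression matrix with *m* genes and *t* tumor
samples, each gene *i* is absolute-z-scored against the cohort:

    absz[i, j] = |ex(Gi, Tj) − mean_i| / SD_i,

with mean_i and SD_i (t−1 denominator) computed across the *t* samples.
The DEPTH2 score of sample *j* is the standard deviation (m−1
denominator) of its column of absolute z-scores.  A tight, synchronous
transcriptome — most genes deviating from the cohort centre by a similar
normalized amount — scores low; asynchronous alteration levels across
genes score high, which is the signature of intratumor heterogeneity.

No normal reference is required: the cohort itself provides the per-gene
location and scale.  Scores are therefore cohort-dependent by design —
adding or removing samples changes the per-gene statistics and hence
every score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from depth2.io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AbsZMatrix",
    "log_transform",
    "absolute_zscore",
    "depth2_score",
    "score_expression",
    "purity_adjust",
    "tumor_mutation_burden",
    "ZERO_VARIANCE_TOL",
]

#: per-gene SDs at or below this are treated as zero variance and dropped
ZERO_VARIANCE_TOL = 1e-12


@dataclass
class AbsZMatrix:
    """Per-gene absolute z-scores plus the statistics that produced them.

    ``absz`` holds only the retained (non-constant) genes; ``gene_means``
    and ``gene_sds`` are aligned to it, and ``dropped_genes`` lists the
    zero-variance gene ids that were removed.
    """

    absz: pd.DataFrame
    gene_means: pd.Series
    gene_sds: pd.Series
    dropped_genes: list[str]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.absz.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.absz.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.absz.shape


def log_transform(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every value v by log2(v + 1).

    A no-op (with a warning) when the matrix is already on the log2(x+1)
    scale; negative input values are a hard error with coordinates.
    """
    if mat.scale == "log2p1":
        logger.warning("matrix already log2(x+1)-scaled; log_transform is a no-op")
        return mat.copy()
    vals = mat.data.to_numpy()
    if (vals < 0).any():
        i, j = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"negative expression value {vals[i, j]} at gene "
            f"{mat.data.index[i]!r}, sample {mat.data.columns[j]!r}; "
            "log2(v+1) requires v >= 0"
        )
    out = pd.DataFrame(np.log2(vals + 1.0), index=mat.data.index, columns=mat.data.columns)
    return ExpressionMatrix(out, scale="log2p1")


def absolute_zscore(
    mat: ExpressionMatrix, ref_samples: Sequence[str] | None = None
) -> AbsZMatrix:
    """Absolute z-score every gene against the cohort.

    By default the reference population is the full set of supplied
    samples.  ``ref_samples`` freezes the per-gene means/SDs to a
    designated subset (e.g. tumors only) while still scoring every
    column — useful for scoring normal controls against tumor
    statistics.  Genes with zero variance in the reference are dropped
    and recorded.
    """
    m, t = mat.shape
    if m < 2 or t < 2:
        raise ValueError(f"need at least 2 genes and 2 samples, got m={m}, t={t}")
    if ref_samples is not None:
        ref_samples = list(ref_samples)
        missing = [s for s in ref_samples if s not in mat.data.columns]
        if missing:
            raise ValueError(f"ref_samples not in matrix: {missing}")
        if len(ref_samples) < 2:
            raise ValueError("need at least 2 reference samples")
        ref = mat.data[ref_samples]
    else:
        ref = mat.data
    means = ref.mean(axis=1)
    sds = ref.std(axis=1, ddof=1)
    keep = sds > ZERO_VARIANCE_TOL
    dropped = list(sds.index[~keep])
    if not keep.any():
        raise ValueError("no informative genes: every gene has zero variance")
    if dropped:
        logger.info("dropped %d zero-variance gene(s)", len(dropped))
    absz = mat.data.loc[keep].sub(means[keep], axis=0).abs().div(sds[keep], axis=0)
    return AbsZMatrix(absz, means[keep], sds[keep], dropped)


def depth2_score(absz: AbsZMatrix) -> pd.DataFrame:
    """Per-sample DEPTH2 score: SD of the sample's absolute z-scores.

    Returns a DataFrame indexed by sample_id with columns ``depth2``
    (non-negative) and ``n_genes_used`` (the retained gene count m').
    """
    mprime = absz.shape[0]
    if mprime < 2:
        raise ValueError(f"need at least 2 retained genes to score, got {mprime}")
    scores = absz.absz.std(axis=0, ddof=1)
    out = pd.DataFrame({"depth2": scores, "n_genes_used": mprime})
    out.index.name = "sample_id"
    return out


def score_expression(
    mat: ExpressionMatrix,
    *,
    already_log2: bool = False,
    ref_samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Convenience pipeline: (log2 transform) → absolute z → score."""
    if mat.scale == "linear" and not already_log2:
        mat = log_transform(mat)
    return depth2_score(absolute_zscore(mat, ref_samples=ref_samples))


def purity_adjust(
    scores: pd.DataFrame, cohort: pd.DataFrame, purity_col: str = "purity"
) -> pd.DataFrame:
    """Divide each score by the sample's tumor-cell proportion.

    Samples without a purity value keep their raw score and get a
    missing adjusted score; purity outside (0, 1] is an error.  With
    purity ≤ 1 the adjusted score is always ≥ the raw score.
    """
    if purity_col not in cohort.columns:
        raise ValueError(f"cohort table lacks purity column {purity_col!r}")
    purity = pd.to_numeric(cohort[purity_col], errors="raise").reindex(scores.index)
    present = purity.notna()
    bad = list(purity.index[present & ((purity <= 0) | (purity > 1))])
    if bad:
        raise ValueError(f"purity outside (0,1] for samples {bad}")
    out = scores.copy()
    out["depth2_purity_adjusted"] = out["depth2"] / purity
    n_missing = int((~present).sum())
    if n_missing:
        logger.info("%d sample(s) lack purity; adjusted score left missing", n_missing)
    return out


def tumor_mutation_burden(muts: pd.DataFrame, samples: Sequence[str]) -> pd.Series:
    """Total somatic mutation count per sample.

    Samples requested but absent from the mutation table count 0.
    """
    counts = muts["sample_id"].value_counts() if len(muts) else pd.Series(dtype=int)
    out = counts.reindex(list(samples), fill_value=0).astype(int)
    out.name = "tmb"
    out.index.name = "sample_id"
    return out
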