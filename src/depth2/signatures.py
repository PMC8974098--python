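"""Per-sample signature scoring: ssGSEA and two-signature log ratios.

The ssGSEA variant implemented here ranks genes within each sample
(average ranks for ties), walks the genes in descending-expression
order, and accumulates the difference between the weighted in-set
cumulative distribution (rank weights raised to the exponent ``weight``,
normalized to sum 1 within the set) and the uniform out-of-set
cumulative distribution.  With ``weight=0`` this reduces to the
unweighted KS-like difference of the two empirical CDFs.  Because only
ranks enter, scores are invariant to any monotone transform of the
expression values, so matrices may be scored on either scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from depth2.io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["ssgsea", "signature_ratio"]


def _sample_enrichment(
    expr: np.ndarray,
    gene_ids: np.ndarray,
    ranks: np.ndarray,
    in_set: np.ndarray,
    weight: float,
) -> float:
    """Running-sum enrichment score for one sample.

    ``ranks`` are ascending average ranks (top-expressed gene has rank
    N); ordering ties are broken by gene id so the result does not
    depend on input row order.
    """
    order = np.lexsort((gene_ids, -expr))
    hit = in_set[order]
    w = ranks[order] ** weight
    w_hit = np.where(hit, w, 0.0)
    p_in = np.cumsum(w_hit) / w_hit.sum()
    n_out = (~in_set).sum()
    p_out = np.cumsum(~hit) / n_out
    return float((p_in - p_out).sum())


def ssgsea(
    mat: ExpressionMatrix,
    sets: GeneSetCollection,
    *,
    weight: float = 0.25,
    min_overlap: int = 2,
    normalize: str | None = None,
) -> pd.DataFrame:
    """Single-sample gene-set enrichment scores.

    Parameters
    ----------
    mat
        Expression matrix; only within-sample ranks are used.
    sets
        Gene sets to score.  Sets sharing fewer than ``min_overlap``
        genes with the matrix (or spanning every gene, leaving no
        out-of-set background) are skipped with a warning.
    weight
        Rank-weight exponent (0 gives the unweighted ECDF difference;
        0.25 is common ssGSEA practice).
    normalize
        ``None`` (default) leaves raw running-sum scores; ``"range"``
        divides the whole table by its cohort-wide ES range for users
        matching other toolchains.

    Returns
    -------
    DataFrame of enrichment scores, signatures × samples, with the
    parameters recorded in ``.attrs``.
    """
    if weight < 0:
        raise ValueError(f"weight must be >= 0, got {weight}")
    if normalize not in (None, "range"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    gene_ids = np.asarray(mat.gene_ids)
    values = mat.values
    # ascending average ranks per sample: the top gene gets rank N
    ranks = pd.DataFrame(values).rank(axis=0, method="average").to_numpy()
    rows: dict[str, list[float]] = {}
    for name, members in sets.items():
        in_set = np.isin(gene_ids, list(set(members)))
        k = int(in_set.sum())
        if k < min_overlap:
            logger.warning(
                "skipping set %r: %d overlapping gene(s) < min_overlap=%d",
                name, k, min_overlap,
            )
            continue
        if k == len(gene_ids):
            logger.warning("skipping set %r: no out-of-set genes", name)
            continue
        rows[name] = [
            _sample_enrichment(values[:, j], gene_ids, ranks[:, j], in_set, weight)
            for j in range(values.shape[1])
        ]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=mat.sample_ids)
    out.index.name = "signature"
    if normalize == "range" and out.size:
        span = float(out.to_numpy().max() - out.to_numpy().min())
        if span > 0:
            out = out / span
    out.attrs["weight"] = weight
    out.attrs["normalize"] = normalize
    return out


def signature_ratio(
    mat: ExpressionMatrix,
    set_a: list[str],
    set_b: list[str],
    *,
    pseudocount: bool = True,
) -> pd.Series:
    """log2 ratio of two signatures' geometric-mean expression per sample.

    On the log2 scale this is the arithmetic mean over ``set_a`` minus
    the mean over ``set_b`` (the log2 geometric-mean ratio of the
    pseudocounted linear values).  For a linear-scale matrix,
    ``pseudocount=True`` uses log2(v+1) and ``pseudocount=False`` uses
    log2(v) (strictly positive values required); without the
    pseudocount the ratio is invariant to global rescaling.
    """
    a = [g for g in dict.fromkeys(set_a) if g in mat.data.index]
    b = [g for g in dict.fromkeys(set_b) if g in mat.data.index]
    if not a or not b:
        which = "set_a" if not a else "set_b"
        raise ValueError(f"{which} shares no genes with the matrix")
    if mat.scale == "log2p1":
        logvals = mat.data
    elif pseudocount:
        logvals = np.log2(mat.data + 1.0)
    else:
        if (mat.data.to_numpy() <= 0).any():
            raise ValueError("pseudocount=False requires strictly positive values")
        logvals = np.log2(mat.data)
    ratio = logvals.loc[a].mean(axis=0) - logvals.loc[b].mean(axis=0)
    ratio.name = "log2_ratio"
    ratio.index.name = "sample_id"
    return ratio
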