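"""Inferential battery for score–covariate analysis.

Median-split group definition, Spearman correlation screens with
Benjamini–Hochberg FDR over caller-declared families, one-sided
Mann–Whitney U and Kruskal–Wallis group comparisons, Kaplan–Meier
estimation and the (optionally stratified) two-group log-rank test.

Standard tests are delegated to scipy/statsmodels/lifelines; this module
owns group definition, family bookkeeping and the stratified log-rank
accumulation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTestResult",
    "SurvivalComparison",
    "median_split",
    "spearman_screen",
    "mannwhitney_one_sided",
    "kruskal_wallis",
    "km_logrank",
]

#: largest combined sample size for the exact Mann–Whitney branch
MW_EXACT_MAX_N = 20


@dataclass
class GroupTestResult:
    """Outcome of a two-or-more-group location comparison."""

    test: str
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    alternative: str | None = None
    method: str | None = None


@dataclass
class SurvivalComparison:
    """KM curves for two groups plus the log-rank comparison."""

    groups: pd.Series
    curves: dict[str, pd.DataFrame]
    statistic: float
    p_value: float
    events: dict[str, int] = field(default_factory=dict)


def median_split(scores: pd.Series | pd.DataFrame) -> pd.Series:
    """Label samples strictly above the median 'high', strictly below 'low'.

    Samples exactly at the median are excluded (their count is logged).
    Requires at least four scored samples; all-identical scores make the
    split impossible.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["depth2"]
    scores = scores.dropna()
    if len(scores) < 4:
        raise ValueError(f"median split needs >= 4 scored samples, got {len(scores)}")
    if scores.nunique() == 1:
        raise ValueError("median split impossible: all scores identical")
    med = scores.median()
    labels = pd.Series(
        np.where(scores > med, "high", np.where(scores < med, "low", "")),
        index=scores.index,
        name="depth2_group",
    )
    n_excluded = int((labels == "").sum())
    if n_excluded:
        logger.info("median split excluded %d sample(s) at the median", n_excluded)
    return labels[labels != ""]


def spearman_screen(
    x: pd.Series, ys: pd.DataFrame, family: str = "default"
) -> pd.DataFrame:
    """Spearman correlation of ``x`` against every column of ``ys``.

    Pairwise-complete observations; rho is computed on average-ranked
    data with the t-approximation p-value.  BH adjustment is applied
    within the declared ``family``; pairs with fewer than three complete
    observations or a constant column are flagged undefined and excluded
    from the FDR family.
    """
    rows = []
    for name in ys.columns:
        y = pd.to_numeric(ys[name], errors="coerce")
        pair = pd.concat([x, y], axis=1, keys=["x", "y"]).dropna()
        n = len(pair)
        if n < 3 or pair["x"].nunique() == 1 or pair["y"].nunique() == 1:
            rows.append(
                dict(variable=name, rho=np.nan, p_value=np.nan, n_pairs=n,
                     defined=False)
            )
            continue
        rho, p = stats.spearmanr(pair["x"], pair["y"])
        rows.append(
            dict(variable=name, rho=float(rho), p_value=float(p), n_pairs=n,
                 defined=True)
        )
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    defined = out["defined"].to_numpy()
    if defined.any():
        out.loc[defined, "fdr"] = multipletests(
            out.loc[defined, "p_value"], method="fdr_bh"
        )[1]
    out["family"] = family
    return out.drop(columns="defined")


def mannwhitney_one_sided(
    a, b, alternative: str = "greater"
) -> GroupTestResult:
    """One-sided Mann–Whitney U test of ``a`` versus ``b``.

    Exact null distribution when the combined n ≤ 20 with no ties;
    otherwise the normal approximation with tie and continuity
    corrections.
    """
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= MW_EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return GroupTestResult(
        test="mannwhitney_one_sided",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes={"a": int(a.size), "b": int(b.size)},
        alternative=alternative,
        method=method,
    )


def kruskal_wallis(groups) -> GroupTestResult:
    """Kruskal–Wallis H test across three or more groups.

    ``groups`` is a mapping label → values or a sequence of value
    arrays.  Fewer than three groups is an error (use the Mann–Whitney
    test for two classes).  When every value is identical, H = 0 and
    p = 1 by convention.
    """
    if isinstance(groups, dict):
        labels = list(groups)
        arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        labels = [str(i) for i in range(len(arrays))]
    if len(arrays) < 3:
        raise ValueError(
            "Kruskal–Wallis needs >= 3 groups; use mannwhitney_one_sided for two"
        )
    if any(arr.size == 0 for arr in arrays):
        raise ValueError("every group must be non-empty")
    sizes = {lab: int(arr.size) for lab, arr in zip(labels, arrays)}
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return GroupTestResult("kruskal_wallis", 0.0, 1.0, sizes, method="chi2")
    h, p = stats.kruskal(*arrays)
    return GroupTestResult("kruskal_wallis", float(h), float(p), sizes, method="chi2")


def _logrank_terms(
    times: np.ndarray, events: np.ndarray, in_a: np.ndarray
) -> tuple[float, float]:
    """Observed-minus-expected events in group a, and its variance.

    The standard Mantel–Haenszel 2×2-table accumulation over distinct
    event times.
    """
    o_minus_e = 0.0
    var = 0.0
    for tt in np.unique(times[events == 1]):
        at_risk = times >= tt
        n = int(at_risk.sum())
        na = int((at_risk & in_a).sum())
        d = int(((times == tt) & (events == 1)).sum())
        da = int(((times == tt) & (events == 1) & in_a).sum())
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (n - d) * na * (n - na) / (n**2 * (n - 1))
    return o_minus_e, var


def km_logrank(
    cohort: pd.DataFrame,
    groups: pd.Series,
    endpoint: str = "os",
    strata: pd.Series | None = None,
) -> SurvivalComparison:
    """Kaplan–Meier curves per group and the two-group log-rank test.

    ``endpoint`` selects the ``{endpoint}_time`` / ``{endpoint}_event``
    cohort columns.  A group with zero events triggers a warning but the
    test is still computed.  ``strata`` (off by default) sums the
    O−E and variance terms within each stratum before forming the
    chi-square — the stratified Mantel–Haenszel log-rank.
    """
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    for col in (tcol, ecol):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks endpoint column {col!r}")
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    data = cohort[[tcol, ecol]].reindex(groups.index).dropna()
    groups = groups.reindex(data.index)
    times = data[tcol].to_numpy(dtype=float)
    events = data[ecol].to_numpy(dtype=int)

    curves: dict[str, pd.DataFrame] = {}
    n_events: dict[str, int] = {}
    for lab in labels:
        mask = (groups == lab).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {lab!r} has no samples with endpoint data")
        n_events[lab] = int(events[mask].sum())
        if n_events[lab] == 0:
            warnings.warn(f"group {lab!r} has zero events", stacklevel=2)
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(lab))
        curve = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            }
        )
        curve["at_risk"] = (
            kmf.event_table["at_risk"].reindex(curve["time"]).to_numpy()
        )
        curves[str(lab)] = curve

    in_a = (groups == labels[0]).to_numpy()
    if strata is None:
        res = logrank_test(
            times[in_a], times[~in_a], events[in_a], events[~in_a]
        )
        stat, p = float(res.test_statistic), float(res.p_value)
    else:
        strata = strata.reindex(data.index)
        o_minus_e = 0.0
        var = 0.0
        for s in strata.dropna().unique():
            m = (strata == s).to_numpy()
            ome, v = _logrank_terms(times[m], events[m], in_a[m])
            o_minus_e += ome
            var += v
        stat = o_minus_e**2 / var if var > 0 else 0.0
        p = float(stats.chi2.sf(stat, df=1))
    return SurvivalComparison(
        groups=groups, curves=curves, statistic=stat, p_value=p, events=n_events
    )
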