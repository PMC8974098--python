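"""Bulk-tumor clone-mixture simulator with known ground truth.

Each simulated tumor is a purity-weighted mixture of k clone expression
profiles and a shared normal (baseline) profile, observed with additive
log-scale noise.  Clones form a linear genealogy: clone 1 is the
baseline plus an independent Gaussian perturbation on a random fraction
of genes, and each later clone inherits its parent's alterations and
adds its own on a fresh random gene subset.  Bulk alteration magnitudes
therefore span cellular fractions from fully clonal (shared by all
clones) down to subclonal (private to one clone), so the per-sample
dispersion of absolute z-scores — the ITH score — grows with the number
of clones.  A flat mixture of mutually independent clones would instead
average alterations away (bulk perturbation variance shrinking like
1/k), inverting that relationship.

Everything operates directly on the log2(x+1) scale and is fully
reproducible from the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from depth2.io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "truth_join",
    "simulate_survival",
]


@dataclass
class SimulationConfig:
    """Generative settings for one simulated cohort.

    ``clones_per_tumor`` may be a fixed int, an inclusive ``(lo, hi)``
    2-tuple sampled uniformly per tumor, or an explicit list of length
    ``n_tumors``.  ``purity`` is a fixed fraction or a ``(lo, hi)``
    uniform range over (0, 1].  ``perturbation_sd`` and ``noise_sd`` are
    in log2 units.
    """

    n_genes: int = 500
    n_tumors: int = 100
    n_normals: int = 50
    clones_per_tumor: int | tuple[int, int] | Sequence[int] = (1, 8)
    fraction_perturbed: float = 0.2
    perturbation_sd: float = 1.0
    clone_mixing: str = "dirichlet"  # or "uniform" (equal weights)
    dirichlet_alpha: float = 1.0
    purity: float | tuple[float, float] = 1.0
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_tumors < 1 or self.n_normals < 0:
            raise ValueError("counts must be positive (n_normals may be 0)")
        if not 0.0 <= self.fraction_perturbed <= 1.0:
            raise ValueError("fraction_perturbed must be in [0, 1]")
        if self.perturbation_sd < 0 or self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.clone_mixing not in ("dirichlet", "uniform"):
            raise ValueError(f"unknown clone_mixing {self.clone_mixing!r}")
        for p in np.atleast_1d(np.asarray(self.purity, dtype=float)):
            if not 0.0 < p <= 1.0:
                raise ValueError("purity must lie in (0, 1]")


@dataclass
class SimulatedCohort:
    """Expression matrix (tumors + normals) plus the per-sample truth table.

    Truth columns: ``k`` (clone count, 0 for normals), ``purity`` (NaN
    for normals), ``is_normal``, ``clone_weights`` (semicolon-joined).
    """

    matrix: ExpressionMatrix
    truth: pd.DataFrame
    config: SimulationConfig
    clip_rate: float = 0.0


def _resolve_clone_counts(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    k = cfg.clones_per_tumor
    if isinstance(k, (int, np.integer)):
        ks = np.full(cfg.n_tumors, int(k))
    elif isinstance(k, tuple) and len(k) == 2:
        ks = rng.integers(int(k[0]), int(k[1]) + 1, size=cfg.n_tumors)
    else:
        ks = np.asarray(list(k), dtype=int)
        if ks.size != cfg.n_tumors:
            raise ValueError(
                f"clones_per_tumor list length {ks.size} != n_tumors {cfg.n_tumors}"
            )
    if (ks < 1).any():
        raise ValueError("clones_per_tumor must be >= 1")
    return ks


def _resolve_purity(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.purity, tuple):
        lo, hi = cfg.purity
        return rng.uniform(lo, hi, size=cfg.n_tumors)
    return np.full(cfg.n_tumors, float(cfg.purity))


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort of bulk tumors and normal controls.

    Identical configs (including seed) produce bit-identical cohorts.
    Values are clipped at 0 to stay in the valid log2(x+1) range; the
    clipping rate is recorded and warned about above 5%.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_genes
    baseline = np.clip(rng.normal(cfg.baseline_mean, cfg.baseline_sd, m), 0.0, None)
    ks = _resolve_clone_counts(cfg, rng)
    purities = _resolve_purity(cfg, rng)
    n_pert = int(round(cfg.fraction_perturbed * m))

    columns: dict[str, np.ndarray] = {}
    rows = []
    n_clipped = 0
    for j in range(cfg.n_tumors):
        k = int(ks[j])
        clones = np.empty((k, m))
        profile = baseline.copy()
        for c in range(k):
            if n_pert and cfg.perturbation_sd > 0:
                idx = rng.choice(m, size=n_pert, replace=False)
                profile = profile.copy()
                profile[idx] += rng.normal(0.0, cfg.perturbation_sd, n_pert)
            clones[c] = profile
        if k == 1:
            w = np.ones(1)  # exact: a single clone IS the tumor signal
        elif cfg.clone_mixing == "dirichlet":
            w = rng.dirichlet(np.full(k, cfg.dirichlet_alpha))
        else:
            w = np.full(k, 1.0 / k)
        p = purities[j]
        signal = p * (w @ clones) + (1.0 - p) * baseline
        observed = signal + rng.normal(0.0, cfg.noise_sd, m)
        n_clipped += int((observed < 0).sum())
        sid = f"T{j + 1:03d}"
        columns[sid] = np.clip(observed, 0.0, None)
        rows.append(
            dict(sample_id=sid, k=k, purity=p, is_normal=False,
                 clone_weights=";".join(f"{x:.6g}" for x in w))
        )
    for j in range(cfg.n_normals):
        observed = baseline + rng.normal(0.0, cfg.noise_sd, m)
        n_clipped += int((observed < 0).sum())
        sid = f"N{j + 1:03d}"
        columns[sid] = np.clip(observed, 0.0, None)
        rows.append(
            dict(sample_id=sid, k=0, purity=np.nan, is_normal=True, clone_weights="")
        )

    gene_ids = [f"G{i + 1:04d}" for i in range(m)]
    matrix = ExpressionMatrix(
        pd.DataFrame(columns, index=gene_ids), scale="log2p1"
    )
    truth = pd.DataFrame(rows).set_index("sample_id")
    clip_rate = n_clipped / (m * (cfg.n_tumors + cfg.n_normals))
    if clip_rate > 0.05:
        logger.warning("clipping rate %.1f%% exceeds 5%%", 100 * clip_rate)
    elif clip_rate:
        logger.info("clipping rate %.3f%%", 100 * clip_rate)
    return SimulatedCohort(matrix, truth, cfg, clip_rate)


def truth_join(cohort: SimulatedCohort, scores: pd.DataFrame) -> pd.DataFrame:
    """Join the truth table to a score table on sample id.

    Every simulated sample must be scored; extra score rows are ignored
    with a warning.
    """
    missing = [s for s in cohort.truth.index if s not in scores.index]
    if missing:
        raise ValueError(f"score table lacks simulated samples: {missing}")
    extra = [s for s in scores.index if s not in cohort.truth.index]
    if extra:
        logger.warning("ignoring %d score row(s) not in the cohort", len(extra))
    return cohort.truth.join(scores, how="left")


def simulate_survival(
    truth: pd.DataFrame,
    *,
    baseline_hazard: float = np.log(2) / 1000.0,
    log_hr_per_clone: float = 0.35,
    censor_time: float = 2000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival times whose hazard increases with clone count.

    Hazard for a tumor with k clones is ``baseline_hazard *
    exp(log_hr_per_clone * (k - 1))`` (time unit: days; the default
    baseline gives a median of ~1000 days for a single-clone tumor).
    Administrative censoring at ``censor_time``.  Normal samples are
    excluded.  Returns ``os_time`` / ``os_event`` indexed by sample id.
    """
    rng = np.random.default_rng(seed)
    tumors = truth[~truth["is_normal"].astype(bool)]
    lam = baseline_hazard * np.exp(log_hr_per_clone * (tumors["k"].to_numpy() - 1))
    t = rng.exponential(1.0 / lam)
    event = (t <= censor_time).astype(int)
    out = pd.DataFrame(
        {"os_time": np.minimum(t, censor_time), "os_event": event},
        index=tumors.index,
    )
    out.index.name = "sample_id"
    return out
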