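"""Non-parametric group comparisons for the morphometric read-outs.

The reporting convention follows common practice for imaging cohorts:
observations are first averaged within biological replicate, the
replicate means are compared across groups by the tie-corrected
Kruskal-Wallis H test, and pairwise contrasts use Dunn's rank test with
Holm step-down adjustment.  Raw-observation mode is available for data
without a replicate structure.

H is computed from the rank formula

    H = [ 12 / (N (N+1)) * sum_i R_i^2 / n_i - 3 (N+1) ] / (1 - sum(t^3 - t) / (N^3 - N))

with mid-ranks for ties, and referred to a chi-square with k-1 df.  Dunn's
z for groups i, j uses the mean-rank difference over the tie-corrected
pooled standard error sqrt((N(N+1)/12 - sum(t^3 - t)/(12(N-1))) (1/n_i + 1/n_j)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupData",
    "PairwiseResult",
    "TestResult",
    "groups_from_frame",
    "replicate_means",
    "kruskal_wallis",
    "dunn_holm",
    "compare_groups",
]


@dataclass
class GroupData:
    label: str
    observations: np.ndarray
    replicate_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=float)
        if self.observations.size == 0:
            raise ValueError(f"group {self.label!r} has no observations")
        if self.replicate_ids is not None:
            self.replicate_ids = np.asarray(self.replicate_ids)
            if self.replicate_ids.shape != self.observations.shape:
                raise ValueError("replicate_ids must match observations")


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_holm: float


@dataclass
class TestResult:
    chi2: float  # Kruskal-Wallis H (tie-corrected)
    p: float
    pairwise: list[PairwiseResult]
    medians: dict[str, float]
    n: dict[str, int]


def groups_from_frame(
    df: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    replicate: Optional[str] = "replicate",
) -> list[GroupData]:
    """Build GroupData from a tidy table (one row per observation)."""
    out = []
    rep = replicate if replicate in df.columns else None
    for g, sub in df.groupby(group, sort=True):
        out.append(
            GroupData(
                label=str(g),
                observations=sub[value].to_numpy(),
                replicate_ids=sub[rep].to_numpy() if rep else None,
            )
        )
    return out


def replicate_means(group: GroupData) -> np.ndarray:
    """Mean observation per biological replicate (identity when the group
    has no replicate structure)."""
    if group.replicate_ids is None:
        return group.observations
    s = pd.Series(group.observations).groupby(pd.Series(group.replicate_ids)).mean()
    return s.to_numpy()


def _analysis_values(groups: Sequence[GroupData], use_replicate_means: bool) -> list[np.ndarray]:
    return [replicate_means(g) if use_replicate_means else g.observations for g in groups]


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(
    groups: Sequence[GroupData], use_replicate_means: bool = True
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    vals = _analysis_values(groups, use_replicate_means)
    pooled = np.concatenate(vals)
    n_total = pooled.size
    tie = _tie_term(pooled)
    denom = 1.0 - tie / (n_total**3 - n_total) if n_total > 1 else 0.0
    if denom <= 0:
        return 0.0, 1.0  # all values identical
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for v in vals:
        r = ranks[start : start + v.size]
        h += r.sum() ** 2 / v.size
        start += v.size
    h = (12.0 / (n_total * (n_total + 1.0)) * h - 3.0 * (n_total + 1.0)) / denom
    h = max(h, 0.0)
    p = float(chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def dunn_holm(
    groups: Sequence[GroupData], use_replicate_means: bool = True
) -> list[PairwiseResult]:
    """Dunn's pairwise z tests on pooled mid-ranks with tie-corrected
    variance, Holm-adjusted over all pairs (two-sided)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    vals = _analysis_values(groups, use_replicate_means)
    pooled = np.concatenate(vals)
    n_total = pooled.size
    ranks = rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for v in vals:
        mean_ranks.append(ranks[start : start + v.size].mean())
        sizes.append(v.size)
        start += v.size
    tie = _tie_term(pooled)
    var = n_total * (n_total + 1.0) / 12.0 - tie / (12.0 * (n_total - 1.0)) if n_total > 1 else 0.0
    pairs = list(itertools.combinations(range(len(groups)), 2))
    zs, ps = [], []
    for i, j in pairs:
        se = np.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j])) if var > 0 else 0.0
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        zs.append(z)
        ps.append(float(2.0 * norm.sf(abs(z))) if se > 0 else 1.0)
    if ps:
        _, p_holm, _, _ = multipletests(ps, method="holm")
    else:
        p_holm = []
    return [
        PairwiseResult(pair=(groups[i].label, groups[j].label), z=float(z), p_raw=float(p), p_holm=float(ph))
        for (i, j), z, p, ph in zip(pairs, zs, ps, p_holm)
    ]


def compare_groups(
    groups: Sequence[GroupData], use_replicate_means: bool = True
) -> TestResult:
    """Full report: H, p, Dunn-Holm pairwise results, per-group medians and
    observation counts (medians/n describe the analysed values)."""
    h, p = kruskal_wallis(groups, use_replicate_means)
    vals = _analysis_values(groups, use_replicate_means)
    return TestResult(
        chi2=h,
        p=p,
        pairwise=dunn_holm(groups, use_replicate_means),
        medians={g.label: float(np.median(v)) for g, v in zip(groups, vals)},
        n={g.label: int(v.size) for g, v in zip(groups, vals)},
    )
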