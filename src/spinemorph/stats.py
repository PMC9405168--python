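"""Nonparametric inferential battery: tie-corrected Kruskal–Wallis, Dunn's
pairwise Z post hoc, a Shapiro–Wilk normality gate, and significance codes.

Density data are quotients of small integer counts, so ties are pervasive;
tie corrections are therefore always applied.  The normality check is
advisory only (the analysis path is nonparametric regardless); it is
reported, never used to switch methods.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "PairwiseResult",
    "DegenerateDataError",
    "kruskal_wallis",
    "dunn_posthoc",
    "normality_check",
    "significance_code",
]


class DegenerateDataError(ValueError):
    """All observations identical: rank statistics are undefined."""


@dataclass(frozen=True)
class GroupTestResult:
    """Tie-corrected Kruskal–Wallis H, its degrees of freedom and chi-square p."""

    H: float
    df: int
    p: float


@dataclass(frozen=True)
class PairwiseResult:
    """One Dunn pairwise comparison: Z on mean ranks, raw/adjusted p, code."""

    group_a: str
    group_b: str
    Z: float
    p_raw: float
    p_adjusted: float
    code: str


def _pooled_ranks(groups: Sequence[np.ndarray]) -> tuple[np.ndarray, list[int], float]:
    """Mid-ranks of the pooled sample, group sizes, and the tie term ΣT = Σ(t³ − t)."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    return ranks, sizes, tie_term


def _validate_groups(groups: Sequence) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 1 for g in gs):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(gs)
    if not np.all(np.isfinite(pooled)):
        raise ValueError("observations must be finite")
    if np.unique(pooled).size < 2:
        raise DegenerateDataError("all observations are identical")
    return gs


def kruskal_wallis(groups: Sequence) -> GroupTestResult:
    """Tie-corrected Kruskal–Wallis test of equal medians across k groups.

    H = [12 / (N(N+1))] · Σ nᵢ (R̄ᵢ − (N+1)/2)², divided by the tie
    correction 1 − ΣT/(N³ − N) with T = t³ − t per tie group; p is the
    upper chi-square tail with df = k − 1.
    """
    gs = _validate_groups(groups)
    ranks, sizes, tie_term = _pooled_ranks(gs)
    N = sum(sizes)
    offsets = np.cumsum([0] + sizes)
    H = 0.0
    for i, n_i in enumerate(sizes):
        mean_rank = float(np.mean(ranks[offsets[i] : offsets[i + 1]]))
        H += n_i * (mean_rank - (N + 1) / 2.0) ** 2
    H *= 12.0 / (N * (N + 1))
    correction = 1.0 - tie_term / (N**3 - N)
    if correction <= 0:  # only when all values tie; guarded above
        raise DegenerateDataError("tie correction degenerate")
    H /= correction
    df = len(gs) - 1
    p = float(sps.chi2.sf(H, df))
    return GroupTestResult(H=float(H), df=df, p=p)


def dunn_posthoc(
    groups: Sequence,
    labels: Sequence[str] | None = None,
    adjust: str = "none",
) -> list[PairwiseResult]:
    """Dunn's pairwise post hoc Z comparisons on pooled mean ranks.

    Z_ab = (R̄_a − R̄_b) / sqrt[ (N(N+1)/12 − ΣT/(12(N−1))) (1/n_a + 1/n_b) ]
    with two-sided normal p values.  ``adjust`` ∈ {none, bonferroni, holm};
    the default is no adjustment, matching raw-Z reporting.  Z is
    antisymmetric in the pair ordering.
    """
    if adjust not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    gs = _validate_groups(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValueError("labels must match groups")
    ranks, sizes, tie_term = _pooled_ranks(gs)
    N = sum(sizes)
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        float(np.mean(ranks[offsets[i] : offsets[i + 1]])) for i in range(len(gs))
    ]
    var_core = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    pairs = list(itertools.combinations(range(len(gs)), 2))
    zs, p_raws = [], []
    for a, b in pairs:
        se = np.sqrt(var_core * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        zs.append(float(z))
        p_raws.append(float(2.0 * sps.norm.sf(abs(z))))
    if adjust == "none":
        p_adj = list(p_raws)
    else:
        p_adj = list(multipletests(p_raws, method=adjust)[1])
    return [
        PairwiseResult(
            group_a=labels[a],
            group_b=labels[b],
            Z=z,
            p_raw=p_raw,
            p_adjusted=float(pa),
            code=significance_code(float(pa)),
        )
        for (a, b), z, p_raw, pa in zip(pairs, zs, p_raws, p_adj)
    ]


def normality_check(values: Sequence, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro–Wilk normality test; returns (W, p, is_normal at ``alpha``).

    Advisory: the pipeline always proceeds nonparametrically, but the gate
    is logged alongside results.  Requires 3 ≤ n ≤ 5000.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or not (3 <= arr.size <= 5000):
        raise ValueError("normality check needs a 1-d sample with 3 <= n <= 5000")
    W, p = sps.shapiro(arr)
    return float(W), float(p), bool(p >= alpha)


def significance_code(p: float) -> str:
    """Map a p value to the conventional asterisk code.

    ``**** < 0.0001 <= *** < 0.001 <= ** < 0.01 <= * < 0.05 <= ns``;
    p exactly 0.05 is ns.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
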