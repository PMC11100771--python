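"""Nonparametric group comparisons for loop-length distributions.

The omnibus test is Kruskal-Wallis (tie-corrected H, chi-square reference
with k−1 degrees of freedom).  The all-pairs post hoc is the Steel-Dwass
procedure — the rank-based analogue of Tukey's HSD: each pair of groups is
jointly mid-ranked, the rank-sum statistic is standardised with the
tie-corrected variance, and |t|·√2 is referred to the Studentized-range
distribution over k groups, which controls the family-wise error rate.  For
small groups (any n < 5) the asymptotic reference is unreliable and the
procedure falls back to a max-statistic Monte-Carlo permutation reference,
which is exact up to simulation error.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger("structprof")

__all__ = ["GroupedSamples", "StatsError", "kruskal_wallis", "steel_dwass",
           "pairwise_rank_statistics", "studentized_range_pvalue"]


class StatsError(ValueError):
    pass


@dataclass
class GroupedSamples:
    """Named groups of real values."""

    groups: dict

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise StatsError("need at least 2 groups")
        clean = {}
        for name, vals in self.groups.items():
            arr = np.asarray(vals, dtype=float).ravel()
            if arr.size == 0:
                raise StatsError(f"group {name!r} is empty")
            if not np.all(np.isfinite(arr)):
                raise StatsError(f"group {name!r} contains non-finite values")
            clean[str(name)] = arr
        self.groups = clean

    @property
    def names(self) -> list:
        return list(self.groups)

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def total_n(self) -> int:
        return int(sum(len(v) for v in self.groups.values()))


def kruskal_wallis(samples: GroupedSamples) -> tuple[float, float]:
    """Tie-corrected H and its chi-square (k−1 df) p value."""
    if samples.total_n < 3:
        raise StatsError("need at least 3 observations in total")
    arrays = list(samples.groups.values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*arrays)
    return float(H), float(p)


def _pair_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Standardised tie-corrected rank-sum statistic on the jointly ranked pair."""
    na, nb = len(a), len(b)
    N = na + nb
    ranks = sps.rankdata(np.concatenate([a, b]))
    W = ranks[:na].sum()
    E = na * (N + 1) / 2.0
    V = na * nb / (N * (N - 1.0)) * (np.sum(ranks ** 2) - N * (N + 1.0) ** 2 / 4.0)
    if V <= 0:
        return 0.0
    return float((W - E) / np.sqrt(V))


def pairwise_rank_statistics(samples: GroupedSamples) -> list:
    """[(name_a, name_b, t), ...] for all group pairs."""
    out = []
    for a, b in itertools.combinations(samples.names, 2):
        out.append((a, b, _pair_statistic(samples.groups[a], samples.groups[b])))
    return out


def studentized_range_pvalue(t: float, k: int) -> float:
    """Two-sided adjusted p for a standardised pair statistic via the
    Studentized-range distribution over k groups (df → ∞)."""
    q = abs(t) * np.sqrt(2.0)
    return float(np.clip(sps.studentized_range.sf(q, k, np.inf), 0.0, 1.0))


def steel_dwass(samples: GroupedSamples, method: str = "auto",
                n_permutations: int = 10000, seed: int = 0) -> pd.DataFrame:
    """All-pairs Steel-Dwass comparisons.

    ``method``: ``asymptotic`` (Studentized-range reference), ``permutation``
    (max-statistic Monte-Carlo), or ``auto`` (permutation when any group has
    n < 5).  Returns a table with one row per pair: the standardised rank
    statistic and the family-wise-adjusted p value.
    """
    if any(len(v) < 2 for v in samples.groups.values()):
        raise StatsError("each group needs n >= 2")
    k = samples.k
    stats_obs = pairwise_rank_statistics(samples)
    if method == "auto":
        small = any(len(v) < 5 for v in samples.groups.values())
        if small:
            log.warning("steel_dwass: a group has n < 5; using the permutation reference")
        method = "permutation" if small else "asymptotic"

    if method == "asymptotic":
        rows = [{"group_a": a, "group_b": b, "statistic": t,
                 "p_adjusted": studentized_range_pvalue(t, k), "method": method}
                for a, b, t in stats_obs]
        return pd.DataFrame(rows)
    if method != "permutation":
        raise StatsError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    pooled = np.concatenate(list(samples.groups.values()))
    sizes = [len(v) for v in samples.groups.values()]
    edges = np.cumsum([0] + sizes)
    null_max = np.empty(n_permutations)
    for r in range(n_permutations):
        perm = rng.permutation(pooled)
        groups = [perm[edges[i]:edges[i + 1]] for i in range(k)]
        m = 0.0
        for i, j in itertools.combinations(range(k), 2):
            m = max(m, abs(_pair_statistic(groups[i], groups[j])))
        null_max[r] = m
    rows = []
    for a, b, t in stats_obs:
        p = (1.0 + np.sum(null_max >= abs(t) - 1e-12)) / (n_permutations + 1.0)
        rows.append({"group_a": a, "group_b": b, "statistic": t,
                     "p_adjusted": float(min(p, 1.0)), "method": method})
    return pd.DataFrame(rows)
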