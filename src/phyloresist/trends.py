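"""Nonparametric gradient and group statistics.

Theil-Sen slopes with Mann-Kendall/Kendall tau-b trend tests describe
monotonic change of an index along the continuous invader-cover gradient;
Kruskal-Wallis with Dunn's post hoc compares expansion stages; all families
of p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateInputError, ValidationError


@dataclass(frozen=True)
class TrendResult:
    """Theil-Sen slope plus the Mann-Kendall monotonic-trend test."""

    slope: float
    intercept: float
    tau: float
    s_statistic: int
    p_value: float
    n: int
    method: str = "normal-approx"
    p_adjusted: float | None = None


@dataclass(frozen=True)
class GroupTestResult:
    """Kruskal-Wallis with Dunn's pairwise post hoc (BH-adjusted)."""

    kw_statistic: float
    kw_p: float
    pairwise: list  #: (group_a, group_b, z, p, p_adjusted)
    letters: dict  #: compact letter display per group at alpha = 0.05


def theil_sen(x: Sequence[float], y: Sequence[float]) -> TrendResult:
    """Theil-Sen slope: the median of all pairwise slopes (y_j-y_i)/(x_j-x_i)
    over pairs with distinct x; intercept = median(y - slope*x).

    The Mann-Kendall fields of the returned record are left unset (nan);
    use :func:`mann_kendall` for the full trend test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 2:
        raise ValidationError("need at least 2 points")
    if np.ptp(x) == 0:
        raise DegenerateInputError("slope undefined: all x identical")
    slope, intercept, _, _ = stats.theilslopes(y, x, method="joint")
    return TrendResult(
        slope=float(slope), intercept=float(intercept),
        tau=float("nan"), s_statistic=0, p_value=float("nan"),
        n=int(x.size), method="theil-sen-only",
    )


def _kendall_s(x: np.ndarray, y: np.ndarray) -> int:
    n = x.size
    s = 0
    for i in range(n - 1):
        s += int(np.sum(np.sign(x[i + 1:] - x[i]) * np.sign(y[i + 1:] - y[i])))
    return s


def _tie_groups(v: np.ndarray) -> np.ndarray:
    _, counts = np.unique(v, return_counts=True)
    return counts[counts > 1]


def _kendall_var_s(x: np.ndarray, y: np.ndarray) -> float:
    # Kendall (1970) variance of S with tie corrections in both variables
    n = x.size
    t = _tie_groups(x)
    u = _tie_groups(y)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = np.sum(t * (t - 1) * (2 * t + 5))
    vu = np.sum(u * (u - 1) * (2 * u + 5))
    v1 = np.sum(t * (t - 1)) * np.sum(u * (u - 1)) / (2.0 * n * (n - 1))
    v2 = 0.0
    if n > 2:
        v2 = (
            np.sum(t * (t - 1) * (t - 2))
            * np.sum(u * (u - 1) * (u - 2))
            / (9.0 * n * (n - 1) * (n - 2))
        )
    return (v0 - vt - vu) / 18.0 + v1 + v2


def mann_kendall(x: Sequence[float], y: Sequence[float]) -> TrendResult:
    """Mann-Kendall monotonic-trend test of y along the gradient x.

    S sums sign(x_j - x_i)*sign(y_j - y_i) over pairs; tau is the
    tie-corrected tau-b.  For n <= 10 with no ties in either variable the
    p-value is the exact permutation-null probability; otherwise it comes
    from the normal approximation with tie-corrected variance and a
    continuity correction.  The Theil-Sen slope and intercept are attached.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("Mann-Kendall needs n >= 3")
    ts = theil_sen(x, y) if np.ptp(x) > 0 else None
    s = _kendall_s(x, y)
    tau = float(stats.kendalltau(x, y, variant="b").statistic)
    if math.isnan(tau):
        tau = 0.0
    no_ties = _tie_groups(x).size == 0 and _tie_groups(y).size == 0
    if x.size <= 10 and no_ties:
        p = float(stats.kendalltau(x, y, method="exact").pvalue)
        method = "exact"
    else:
        var_s = _kendall_var_s(x, y)
        if var_s <= 0:
            p = 1.0
        else:
            z = (s - np.sign(s)) / math.sqrt(var_s)  # continuity correction
            p = float(2.0 * stats.norm.sf(abs(z)))
        method = "normal-approx"
    return TrendResult(
        slope=ts.slope if ts else float("nan"),
        intercept=ts.intercept if ts else float("nan"),
        tau=tau, s_statistic=int(s), p_value=min(p, 1.0),
        n=int(x.size), method=method,
    )


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


#: permutation-null distributions of the KW statistic, keyed by the group
#: sizes and the pooled rank multiset (both fully determine the null)
_KW_NULL_CACHE: dict = {}
_KW_PERMUTATIONS = 9999
_KW_EXACT_MAX_N = 30


def _kw_statistic(rank_sums: np.ndarray, sizes: np.ndarray, n: int, tie_corr: float) -> np.ndarray:
    h = 12.0 / (n * (n + 1)) * ((rank_sums**2) / sizes).sum(axis=-1) - 3.0 * (n + 1)
    return h / tie_corr


def _kw_permutation_p(values: list[np.ndarray], h_obs: float) -> float:
    """Exact-size Kruskal-Wallis p from the permutation null of H.

    The chi-squared approximation is conservative for the tiny groups this
    design uses (4 plots per stage); the permutation null restores the
    nominal size.  The null depends only on the group sizes and the pooled
    rank multiset, so it is computed once per configuration and cached.
    """
    sizes = np.array([v.size for v in values])
    pooled = np.concatenate(values)
    ranks = stats.rankdata(pooled)
    key = (tuple(sizes), tuple(np.sort(ranks)))
    if key not in _KW_NULL_CACHE:
        n = pooled.size
        ties = _tie_groups(pooled)
        tie_corr = 1.0 - float(np.sum(ties**3 - ties)) / (n**3 - n) if ties.size else 1.0
        rng = np.random.default_rng(12345)  # fixed: the null is data-independent
        perm_idx = np.argsort(rng.random((_KW_PERMUTATIONS, n)), axis=1)
        permuted = ranks[perm_idx]
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        rank_sums = np.stack(
            [permuted[:, bounds[i]:bounds[i + 1]].sum(axis=1) for i in range(len(sizes))],
            axis=1,
        )
        _KW_NULL_CACHE[key] = _kw_statistic(rank_sums, sizes, n, tie_corr)
    null = _KW_NULL_CACHE[key]
    return float((1 + np.sum(null >= h_obs - 1e-12)) / (1 + null.size))


def _dunn_pairs(groups: Mapping[str, Sequence[float]]):
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, v in zip(names, values):
        mean_ranks[name] = ranks[start:start + v.size].mean()
        start += v.size
    ties = _tie_groups(pooled)
    tie_term = float(np.sum(ties**3 - ties)) / (12.0 * (n_total - 1)) if ties.size else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    out = []
    for a, b in itertools.combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = math.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        out.append((a, b, float(z), p))
    return out


def _letter_display(names, sig_pairs) -> dict:
    """Greedy compact-letter display: groups not significantly different share
    a letter.  ``names`` fixes the assignment order (BF -> MB)."""
    letters = {n: "" for n in names}
    groups_assigned: list[set] = []
    for n in names:
        placed = False
        for g in groups_assigned:
            if all((n, m) not in sig_pairs and (m, n) not in sig_pairs for m in g):
                g.add(n)
                placed = True
        if not placed:
            groups_assigned.append({n})
    for li, g in enumerate(groups_assigned):
        ch = chr(ord("a") + li)
        for n in names:
            if n in g:
                letters[n] += ch
    return {n: letters[n] for n in names}


def kruskal_dunn(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> GroupTestResult:
    """Kruskal-Wallis across groups, Dunn's z post hoc, BH-adjusted pairs.

    For small pooled samples (N <= 30) the Kruskal-Wallis p-value comes from
    the cached permutation null of H, which holds the nominal size where the
    chi-squared approximation is conservative; larger samples use the
    asymptotic p.  All-identical data returns H = 0, p = 1 rather than an
    error.  The compact-letter display assigns letters greedily in the
    mapping's key order (stages should be passed BF, LM, HM, MB).
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(v.size == 0 for v in values):
        raise ValidationError("every group needs at least one value")
    if not any(v.size >= 2 for v in values):
        raise ValidationError("at least one group needs >= 2 values")
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*values)
        if pooled.size <= _KW_EXACT_MAX_N:
            p = _kw_permutation_p(values, float(h))
    pairs = _dunn_pairs(groups)
    p_adj = bh_fdr([pr[3] for pr in pairs]) if pairs else []
    pairwise = [
        (a, b, z, praw, float(pa)) for (a, b, z, praw), pa in zip(pairs, p_adj)
    ]
    sig = {(a, b) for a, b, _, _, pa in pairwise if pa <= alpha}
    letters = _letter_display(list(groups), sig)
    return GroupTestResult(
        kw_statistic=float(h), kw_p=float(p), pairwise=pairwise, letters=letters
    )
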