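"""Permutation-based multivariate statistics: ANOSIM, PERMANOVA, Mantel.

Each statistic is computed from its definition on the distance matrix and
tested by permuting sample labels (rows/columns jointly). p-values use the
unbiased estimator (1 + #{permuted >= observed}) / (1 + n_permutations), so
they can never be exactly 0. When the number of distinct label arrangements
is small (or ``n_perm="exact"``), the null is enumerated exhaustively and
the p-value is the exact fraction of arrangements at least as extreme,
counting the observed arrangement itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from skbio import DistanceMatrix


@dataclass
class GroupComparison:
    statistic_name: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    r_squared: float | None = None
    exact: bool = False

    def to_dict(self) -> dict:
        d = {
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "exact": self.exact,
        }
        if self.r_squared is not None:
            d["r_squared"] = self.r_squared
        return d


@dataclass
class MantelResult:
    r: float
    p_value: float
    method: str
    n_permutations: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p_value": self.p_value,
            "method": self.method,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _check_groups(ids, groups) -> np.ndarray:
    labels = np.asarray([groups[i] for i in ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    small = uniq[counts < 2]
    if small.size:
        raise ValueError(f"groups with fewer than 2 samples: {list(small)}")
    return labels


def _distinct_arrangements(labels: np.ndarray):
    """All distinct orderings of the label multiset (as label arrays)."""
    uniq, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    buf = np.empty(n, dtype=labels.dtype)
    counts = counts.copy()

    def rec(pos):
        if pos == n:
            yield buf.copy()
            return
        for k in range(len(uniq)):
            if counts[k] > 0:
                counts[k] -= 1
                buf[pos] = uniq[k]
                yield from rec(pos + 1)
                counts[k] += 1

    yield from rec(0)


def n_distinct_arrangements(labels) -> int:
    from math import factorial
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    n = factorial(len(labels))
    for c in counts:
        n //= factorial(int(c))
    return n


def _perm_test(stat_fn, labels, n_perm, seed, alternative="greater"):
    """Shared permutation machinery; returns (observed, p, n_used, exact)."""
    obs = stat_fn(labels)
    exact_n = n_distinct_arrangements(labels)
    use_exact = n_perm == "exact" or (
        isinstance(n_perm, (int, np.integer)) and n_perm >= exact_n and len(labels) <= 10
    )
    if use_exact:
        stats = np.array([stat_fn(lab) for lab in _distinct_arrangements(labels)])
        hits = int(np.sum(stats >= obs - 1e-12))
        return obs, hits / exact_n, exact_n, True
    rng = np.random.default_rng(seed)
    hits = 0
    lab = labels.copy()
    for _ in range(int(n_perm)):
        rng.shuffle(lab)
        if stat_fn(lab) >= obs - 1e-12:
            hits += 1
    return obs, (1 + hits) / (1 + int(n_perm)), int(n_perm), False


def anosim(
    dm: DistanceMatrix,
    groups,
    n_perm: int | str = 9999,
    seed: int | None = 0,
) -> GroupComparison:
    """Clarke's analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) over the
    ranked off-diagonal distances (average ranks on ties), M = n(n-1)/2.
    """
    labels = _check_groups(dm.ids, groups)
    d = dm.condensed_form()
    ranks = rankdata(d)
    m = len(d)
    n = len(labels)
    iu = np.triu_indices(n, k=1)

    def stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

    obs, p, n_used, exact = _perm_test(stat, labels, n_perm, seed)
    return GroupComparison("ANOSIM R", float(obs), float(p), n_used,
                           seed, exact=exact)


def permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int | str = 9999,
    seed: int | None = 0,
) -> GroupComparison:
    """One-factor permutational multivariate analysis of variance.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous quantity
    per group; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)) and
    R^2 = SS_between / SS_total. Labels are permuted jointly over rows and
    columns of the distance matrix.
    """
    labels = _check_groups(dm.ids, groups)
    n = len(labels)
    d2 = np.asarray(dm.data, dtype=float) ** 2
    iu = np.triu_indices(n, k=1)
    d2u = d2[iu]
    ss_total = d2u.sum() / n
    a = len(np.unique(labels))

    def ss_within(lab):
        ssw = 0.0
        for g in np.unique(lab):
            mask = lab == g
            ng = mask.sum()
            ssw += d2u[mask[iu[0]] & mask[iu[1]]].sum() / ng
        return ssw

    def stat(lab):
        ssw = ss_within(lab)
        ssb = ss_total - ssw
        if ssw == 0:  # perfect separation: infinite pseudo-F
            return np.inf
        return (ssb / (a - 1)) / (ssw / (n - a))

    obs, p, n_used, exact = _perm_test(stat, labels, n_perm, seed)
    ssw = ss_within(labels)
    r2 = (ss_total - ssw) / ss_total
    return GroupComparison("PERMANOVA pseudo-F", float(obs), float(p), n_used,
                           seed, r_squared=float(r2), exact=exact)


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 9999,
    seed: int | None = 0,
) -> MantelResult:
    """Mantel correlation between two distance matrices on identical samples.

    r correlates the off-diagonal elements (Pearson or Spearman); the null
    is built by permuting rows and columns of the second matrix jointly.
    The test is two-sided on |r|.
    """
    if tuple(dm1.ids) != tuple(dm2.ids):
        raise ValueError("distance matrices have mismatched sample sets/order")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    n = dm1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = np.asarray(dm1.data, dtype=float)[iu]
    m2 = np.asarray(dm2.data, dtype=float)
    if method == "spearman":
        x = rankdata(x)

    def corr_with(perm):
        y = m2[np.ix_(perm, perm)][iu]
        if method == "spearman":
            y = rankdata(y)
        xc, yc = x - x.mean(), y - y.mean()
        denom = np.sqrt((xc @ xc) * (yc @ yc))
        return 0.0 if denom == 0 else float(xc @ yc / denom)

    ident = np.arange(n)
    obs = corr_with(ident)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        if abs(corr_with(perm)) >= abs(obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + int(n_perm))
    return MantelResult(obs, p, method, int(n_perm), seed)
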