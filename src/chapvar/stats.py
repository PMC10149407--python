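"""Statistical primitives for the TF-inference cascade.

Rank tests (Kruskal-Wallis, Wilcoxon rank-sum), a one-sided pooled
two-proportion z test, upper-tail hypergeometric probabilities,
Bonferroni / Benjamini-Hochberg adjustment, Spearman correlation and
complete-linkage agglomeration.  Every function returns plain numbers or a
:class:`TestResult`, and each records the method actually used (exact vs
asymptotic, continuity correction on/off) so downstream tables are
auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps


@dataclass
class TestResult:
    """Outcome of one hypothesis test.

    ``method`` names the procedure actually applied (e.g. ``"wilcoxon-exact"``
    vs ``"wilcoxon-normal"``); ``sides`` is ``"one"`` or ``"two"``.
    """

    statistic: float
    p: float
    method: str
    sides: str
    n_per_group: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p-value outside [0, 1]: {self.p}")


def kruskal_wallis(groups: list[list[float]]) -> TestResult:
    """Kruskal-Wallis k-group rank test with mid-rank tie correction.

    Fully tied data (every value identical) carries no rank information and
    returns p = 1 rather than dividing by a zero tie-correction factor.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        raise ValueError("kruskal_wallis: empty group")
    if sum(sizes) < 3:
        raise ValueError("kruskal_wallis needs total N >= 3")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal-wallis", "two", sizes)
    stat, p = _sps.kruskal(*groups)
    return TestResult(float(stat), float(min(p, 1.0)), "kruskal-wallis", "two", sizes)


# combined-sample-size crossover below which the exact Wilcoxon null
# distribution is enumerated (cheap: at most C(12,6)=924 arrangements)
_WILCOXON_EXACT_N = 12


def wilcoxon_ranksum(x: list[float], y: list[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of the null distribution when the combined sample size
    is at most 12 and there are no ties; otherwise the normal approximation
    with mid-rank tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_ranksum: empty sample")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return TestResult(float(x.size * y.size / 2.0), 1.0,
                          "wilcoxon-degenerate", "two", [int(x.size), int(y.size)])
    ties = np.unique(combined).size < combined.size
    if combined.size <= _WILCOXON_EXACT_N and not ties:
        res = _sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "wilcoxon-exact"
    else:
        res = _sps.mannwhitneyu(x, y, alternative="two-sided",
                                method="asymptotic", use_continuity=True)
        method = "wilcoxon-normal"
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      method, "two", [int(x.size), int(y.size)])


def two_proportion_greater(x1: int, n1: int, x2: int, n2: int,
                           continuity: bool = True) -> TestResult:
    """One-sided pooled-proportion z test of H1: p1 > p2.

    The continuity correction (on by default, mirroring R's ``prop.test``)
    shrinks the observed difference toward zero but never past it, so equal
    proportions give z = 0, p = 0.5 with or without correction.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("two_proportion_greater: trials must be >= 1")
        if not 0 <= x <= n:
            raise ValueError("two_proportion_greater: successes outside [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    d = p1 - p2
    if continuity:
        cc = min(0.5 * (1.0 / n1 + 1.0 / n2), abs(d))
        d = d - math.copysign(cc, d) if d != 0 else 0.0
    z = 0.0 if se == 0.0 else d / se
    p = float(_sps.norm.sf(z))
    method = "two-proportion-z" + ("-cc" if continuity else "")
    return TestResult(float(z), p, method, "one", [n1, n2])


def hypergeometric_ge(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("hypergeometric_ge: need 0 <= K, n <= N")
    if not 0 <= k <= min(K, n):
        raise ValueError("hypergeometric_ge: need 0 <= k <= min(K, n)")
    return float(_sps.hypergeom.sf(k - 1, N, K, n))


def adjust(ps: list[float], method: str) -> list[float]:
    """Multiple-testing adjustment: ``bonferroni`` or ``bh`` (step-up).

    Input order is preserved; adjusted values are capped at 1 and always
    dominate the raw p-values.
    """
    p = np.asarray(ps, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("adjust: p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        out = np.minimum(1.0, m * p)
    elif method == "bh":
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
        out = np.empty(m)
        out[order] = ranked
    else:
        raise ValueError(f"adjust: unknown method {method!r}")
    return [float(v) for v in out]


def spearman(x: list[float], y: list[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman: need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman: correlation undefined for a constant vector")
    return float(_sps.spearmanr(x, y).statistic)


@dataclass
class Dendrogram:
    """Agglomeration record in scipy linkage layout.

    ``merges`` has one row per merge: (cluster a, cluster b, height, size),
    with original observations numbered 0..n-1 and merged clusters n, n+1, ...
    ``leaf_order`` is the left-to-right leaf sequence of the dendrogram.
    """

    labels: list[str]
    merges: np.ndarray
    leaf_order: list[str]


def hclust_complete(d: np.ndarray, labels: list[str]) -> Dendrogram:
    """Complete-linkage agglomerative clustering.

    Naive O(n^3) agglomeration with a deterministic tie-break: among pairs at
    the minimal distance the one with the smallest (first, second) cluster
    indices merges first.  Merge heights are non-decreasing (complete linkage
    is monotone).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("hclust_complete: matrix/label shape mismatch")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("hclust_complete: distance matrix must be symmetric with zero diagonal")
    if n < 2:
        raise ValueError("hclust_complete: need at least 2 observations")

    # cluster id -> (member set, current index row in work matrix)
    work = d.copy()
    active: dict[int, int] = {i: i for i in range(n)}  # cluster id -> row index
    sizes = {i: 1 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        ids = sorted(active)
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                dist = work[active[a], active[b]]
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, a, b)
        dist, a, b = best
        # complete linkage: new distances are maxima of the two rows
        ra, rb = active[a], active[b]
        newrow = np.maximum(work[ra], work[rb])
        work[ra] = newrow
        work[:, ra] = newrow
        work[ra, ra] = 0.0
        del active[a], active[b]
        active[next_id] = ra
        sizes[next_id] = sizes[a] + sizes[b]
        children[next_id] = (a, b)
        merges[step] = (a, b, dist, sizes[next_id])
        next_id += 1

    def _leaves(cid: int) -> list[int]:
        if cid < n:
            return [cid]
        a, b = children[cid]
        return _leaves(a) + _leaves(b)

    order = [labels[i] for i in _leaves(next_id - 1)]
    return Dendrogram(list(labels), merges, order)
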