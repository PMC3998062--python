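"""Nonparametric statistics battery for the group comparisons.

All tests are rank-based and report two-sided p-values: Mann-Whitney U for
two independent groups (exact enumeration for small samples, normal
approximation with tie and continuity corrections otherwise), Kruskal-Wallis
for several groups, Friedman for repeated measures, Spearman rank
correlation, and the Bonferroni-Holm step-down adjustment for post-hoc
families.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, UndefinedMetricError

#: total sample size up to which the Mann-Whitney p-value is enumerated exactly
EXACT_CROSSOVER = 16


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    pvalue: float
    method: str
    n: tuple[int, ...]
    degenerate: bool = False

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney(x, y, mode: str = "auto", *, continuity: bool = True) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    ``mode='exact'`` (or total n <= 16 under ``'auto'``) enumerates the
    permutation distribution of U over all assignments of the pooled
    midranks, which remains valid under ties; otherwise the normal
    approximation with tie correction (and, by default, continuity
    correction) is used.  Without continuity correction the two-group
    Kruskal-Wallis test is its exact chi-square equivalent.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    if np.ptp(pooled) == 0.0:
        return TestResult(statistic=u_obs, pvalue=1.0, method="mwt-degenerate",
                          n=(nx, ny), degenerate=True)
    exact = mode == "exact" or (mode == "auto" and nx + ny <= EXACT_CROSSOVER)
    if mode not in ("auto", "exact", "approx"):
        raise ParameterError(f"unknown mode {mode!r}")
    if exact:
        idx = np.fromiter(
            (i for comb in combinations(range(nx + ny), nx) for i in comb),
            dtype=np.intp,
        ).reshape(-1, nx)
        u_all = ranks[idx].sum(axis=1) - nx * (nx + 1) / 2
        eps = 1e-9
        p = 2 * min((u_all <= u_obs + eps).mean(), (u_all >= u_obs - eps).mean())
        return TestResult(statistic=u_obs, pvalue=min(1.0, float(p)),
                          method="mwt-exact", n=(nx, ny))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=continuity)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                      method="mwt-approx", n=(nx, ny))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p with g-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ParameterError("need >= 2 non-empty groups")
    ns = tuple(g.size for g in groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0.0:
        return TestResult(statistic=0.0, pvalue=1.0, method="kwt-degenerate",
                          n=ns, degenerate=True)
    h, p = sps.kruskal(*groups)
    return TestResult(statistic=float(h), pvalue=float(p), method="kwt", n=ns)


def friedman(blocked) -> TestResult:
    """Friedman chi-square from within-block midranks (complete design).

    ``blocked`` is an (n_blocks, k_treatments) array; p from chi-square with
    k-1 degrees of freedom, with the standard tie correction.
    """
    data = np.asarray(blocked, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ParameterError("blocked design must be 2-D with k >= 2 treatments")
    if np.isnan(data).any():
        raise ParameterError("incomplete blocks: design contains missing values")
    n, k = data.shape
    ranks = np.apply_along_axis(_midranks, 1, data)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((col_sums ** 2).sum()) - 3 * n * (k + 1)
    # tie correction: divide by 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts ** 3 - counts).sum())
    denom = 1.0 - tie_sum / (n * k * (k * k - 1))
    if denom <= 0.0:
        return TestResult(statistic=0.0, pvalue=1.0, method="ft-degenerate",
                          n=(n, k), degenerate=True)
    chi2 /= denom
    p = float(sps.chi2.sf(chi2, k - 1))
    return TestResult(statistic=float(chi2), pvalue=p, method="ft", n=(n, k))


def holm_adjust(pvalues) -> list[float]:
    """Bonferroni-Holm step-down adjusted p-values, in the original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def spearman(x, y, mode: str = "auto") -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    The coefficient is the Pearson correlation of midranks.  For n <= 9 (or
    ``mode='exact'``) the p-value is obtained by full permutation
    enumeration; otherwise the t-distribution approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("samples must have equal length >= 3")
    rx, ry = _midranks(x), _midranks(y)
    if np.ptp(rx) == 0.0 or np.ptp(ry) == 0.0:
        raise UndefinedMetricError("zero rank variance: correlation undefined")
    n = x.size
    r = float(np.corrcoef(rx, ry)[0, 1])
    exact = mode == "exact" or (mode == "auto" and n <= 9)
    if exact:
        from itertools import permutations
        cx = rx - rx.mean()
        cy = ry - ry.mean()
        perms = np.array(list(permutations(cy)))
        r_all = perms @ cx / np.sqrt((cx ** 2).sum() * (cy ** 2).sum())
        p = float((np.abs(r_all) >= abs(r) - 1e-12).mean())
        return TestResult(statistic=r, pvalue=min(1.0, p), method="spearman-exact", n=(n,))
    res = sps.spearmanr(x, y)
    return TestResult(statistic=r, pvalue=float(res.pvalue), method="spearman-t", n=(n,))


def pairwise_mann_whitney_holm(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], dict]:
    """All pairwise Mann-Whitney tests with Holm-adjusted p-values.

    The post-hoc battery applied after a significant Kruskal-Wallis result.
    """
    pairs = list(combinations(sorted(groups), 2))
    raw = [mann_whitney(groups[a], groups[b]) for a, b in pairs]
    adj = holm_adjust([r.pvalue for r in raw])
    return {pair: {"statistic": r.statistic, "p_raw": r.pvalue, "p_holm": a,
                   "n": r.n}
            for pair, r, a in zip(pairs, raw, adj)}
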