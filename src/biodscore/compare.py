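"""Normality-gated two-group comparison, Spearman correlation, star labels.

The two-tiered procedure mirrors common practice for flow-cytometry
population frequencies and BioD scores: Shapiro–Wilk pre-tests normality
in each group at α = 0.05; if either group deviates, a natural-log
transform is applied and normality re-tested; a two-sample t-test (Welch
by default) runs on whichever scale passes, and if neither does, the
comparison falls back to the Mann–Whitney rank test on the original
values.  The full decision trace (pre-test p-values, transform flag,
chosen test) is recorded so every reported p-value is reconstructible.

No multiplicity correction is applied; all p-values are raw.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ComparisonResult",
    "two_tier_compare",
    "spearman_corr",
    "stars",
    "SW_ALPHA",
]

SW_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    test_used: str  # "t_test" | "t_test_log" | "mann_whitney"
    p_two_sided: float
    stars: str
    statistic: float
    normality_trace: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test_used": self.test_used,
            "p_two_sided": self.p_two_sided,
            "stars": self.stars,
            "statistic": self.statistic,
            **{f"trace_{k}": v for k, v in self.normality_trace.items()},
        }


def _shapiro_ok(x, y, pooled: bool) -> tuple[bool, dict]:
    if pooled:
        p = float(stats.shapiro(np.concatenate([x, y])).pvalue)
        return p >= SW_ALPHA, {"sw_p_pooled": p}
    px = float(stats.shapiro(x).pvalue)
    py = float(stats.shapiro(y).pvalue)
    return (px >= SW_ALPHA and py >= SW_ALPHA), {"sw_p_x": px, "sw_p_y": py}


def two_tier_compare(
    x,
    y,
    welch: bool = True,
    pooled_normality: bool = False,
) -> ComparisonResult:
    """Two-tiered normality-gated comparison of two samples.

    1. Shapiro–Wilk per group (α = 0.05; ``pooled_normality=True`` tests
       the concatenated sample instead).
    2. If any group fails and all values are positive, re-test after a
       natural-log transform.
    3. Normal on the original or log scale → two-sample t-test on that
       scale (Welch by default); otherwise Mann–Whitney on the original
       values (exact enumeration when both groups have n <= 8 and no ties,
       normal approximation with tie correction otherwise).

    Both samples need n >= 3 (the Shapiro–Wilk minimum).  Non-positive
    values encountered when the log branch would fire skip the transform
    and go straight to the nonparametric test, flagged in the trace.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3 for the Shapiro-Wilk pre-test")
    trace: dict = {"transform_applied": False, "log_skipped_nonpositive": False}
    ok, t0 = _shapiro_ok(x, y, pooled_normality)
    trace.update({f"raw_{k}": v for k, v in t0.items()})
    scale = "raw"
    if not ok:
        if np.all(x > 0) and np.all(y > 0):
            lx, ly = np.log(x), np.log(y)
            ok, t1 = _shapiro_ok(lx, ly, pooled_normality)
            trace["transform_applied"] = True
            trace.update({f"log_{k}": v for k, v in t1.items()})
            if ok:
                scale = "log"
                x, y = lx, ly
        else:
            trace["log_skipped_nonpositive"] = True
    if ok:
        res = stats.ttest_ind(x, y, equal_var=not welch)
        test_used = "t_test" if scale == "raw" else "t_test_log"
        stat, p = float(res.statistic), float(res.pvalue)
        trace["welch"] = welch
    else:
        method = "exact" if (max(len(x), len(y)) <= 8 and
                             len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)) \
            else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        test_used = "mann_whitney"
        stat, p = float(res.statistic), float(res.pvalue)
        trace["mw_method"] = method
    return ComparisonResult(
        test_used=test_used,
        p_two_sided=p,
        stars=stars(p),
        statistic=stat,
        normality_trace=trace,
    )


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom) if denom > 0 else np.nan


def spearman_corr(x, y, exact: bool | None = None) -> tuple[float, float]:
    """Spearman rank correlation with average-rank tie handling.

    Returns (rho, two-sided p).  The p-value uses the large-sample t
    approximation by default; ``exact=True`` (allowed for n <= 9, and the
    default there when ties are absent is still the approximation — exact
    is opt-in) enumerates all rank permutations of one vector for an exact
    permutation p: P(|rho_perm| >= |rho_obs|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if exact:
        if n > 9:
            raise ValueError("exact permutation p only supported for n <= 9")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rho = _rank_corr(rx, ry)
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
        rhos = (pc @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= np.abs(rho) - 1e-12))
        return rho, p
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def stars(p: float) -> str:
    """Significance stars: p < 0.05 (*), p < 0.01 (**), p < 0.001 (***);
    everything else (including p == 0.05 exactly) is 'ns' — the
    inequalities are strict."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
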