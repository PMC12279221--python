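"""Nonparametric group statistics with false-discovery-rate control.

Thin, policy-carrying wrappers around scipy/statsmodels:

* Mann-Whitney U (independent groups, e.g. younger vs older game scores) —
  exact enumeration for combined n <= 12 without ties, tie-corrected normal
  approximation otherwise;
* Wilcoxon signed-rank (paired conditions, e.g. wFC vs woFC ROI responses)
  — zero differences dropped (Wilcoxon's original rule), exact for n <= 15
  after zero removal, approximation otherwise;
* Spearman rank correlation (game scores vs ROI responses);
* Benjamini-Hochberg step-up adjustment within explicitly declared families
  (by default one family per report table, e.g. the 8 ROI comparisons of a
  group x chromophore table), q = 0.05.

All tests are two-sided. Undefined cases (all differences zero, constant
input) return a flagged result with NaN p rather than raising, so report
builders can show explicit gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError

__all__ = ["TestResult", "mann_whitney", "wilcoxon_signed_rank", "spearman",
           "benjamini_hochberg", "adjust_family"]

EXACT_MW_MAX_N = 12     # combined sample size bound for exact Mann-Whitney
EXACT_WILCOXON_MAX_N = 15   # pairs (after zero removal) bound for exact test


@dataclass
class TestResult:
    statistic: float
    p_raw: float
    n: int
    test_name: str
    p_adjusted: float | None = None
    family: str | None = None
    note: str | None = None

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.p_raw)


def _as_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.size == 0:
        raise ValidationError(f"{name} sample is empty")
    return a


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent samples."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    pooled = np.concatenate([xa, ya])
    ties = len(np.unique(pooled)) < pooled.size
    exact = (xa.size + ya.size) <= EXACT_MW_MAX_N and not ties
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return TestResult(statistic=float(res.statistic), p_raw=float(res.pvalue),
                      n=xa.size + ya.size,
                      test_name="mann-whitney-exact" if exact
                      else "mann-whitney-normal")


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped before ranking; if every difference is
    zero the statistic is undefined and a flagged NaN result is returned.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size != ya.size:
        raise ValidationError("paired samples must have equal length")
    d = xa - ya
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(statistic=float("nan"), p_raw=float("nan"),
                          n=0, test_name="wilcoxon",
                          note="all differences zero — test undefined")
    ties = len(np.unique(np.abs(nz))) < nz.size
    exact = nz.size <= EXACT_WILCOXON_MAX_N and not ties
    res = sps.wilcoxon(xa, ya, zero_method="wilcox", alternative="two-sided",
                       method="exact" if exact else "approx",
                       correction=not exact)
    return TestResult(statistic=float(res.statistic), p_raw=float(res.pvalue),
                      n=int(nz.size),
                      test_name="wilcoxon-exact" if exact else "wilcoxon-normal")


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (Pearson on tie-averaged ranks), two-sided.

    The returned statistic is rho. Constant input gives a flagged NaN result.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size != ya.size:
        raise ValidationError("samples must have equal length")
    if xa.size < 3:
        raise ValidationError("Spearman requires n >= 3")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return TestResult(statistic=float("nan"), p_raw=float("nan"),
                          n=xa.size, test_name="spearman",
                          note="constant input — correlation undefined")
    rho, p = sps.spearmanr(xa, ya)
    return TestResult(statistic=float(rho), p_raw=float(p), n=xa.size,
                      test_name="spearman")


def benjamini_hochberg(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up BH adjustment: adjusted p_(i) = min_{j>=i} p_(j) * m / j,
    capped at 1, returned in input order; reject where adjusted <= q.

    NaN entries (undefined tests) are passed through as NaN and never
    rejected; m counts only the defined tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and np.nanmin(p) < 0 or p.size and np.nanmax(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    adjusted = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    defined = np.isfinite(p)
    if defined.any():
        rej, adj, _, _ = multipletests(p[defined], alpha=q, method="fdr_bh")
        adjusted[defined] = adj
        reject[defined] = rej
    return adjusted, reject


def adjust_family(results: list[TestResult], family: str,
                  q: float = 0.05) -> list[TestResult]:
    """Attach BH-adjusted p-values to a family of test results in place."""
    adj, _ = benjamini_hochberg([r.p_raw for r in results], q=q)
    for r, a in zip(results, adj):
        r.p_adjusted = float(a) if np.isfinite(a) else None
        r.family = family
    return results
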