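"""Rank-based paired tests and multiple-testing adjustment.

The workhorse here is the two-sided Wilcoxon signed-rank test with a fixed,
reproducible convention:

* zero differences are dropped before ranking (Wilcoxon's original treatment);
* tied absolute differences receive midranks;
* for n <= EXACT_N_MAX non-zero pairs the p-value comes from the exact
  conditional null distribution of W+ given the observed (mid)ranks, computed
  by dynamic programming over all 2^n sign assignments;
* for larger n a normal approximation with tie correction and a 0.5
  continuity correction is used.

The exact distribution is evaluated on doubled ranks (midranks are multiples
of 1/2, so doubling makes them integers) which keeps the convolution purely
integral and the p-values free of float-comparison artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "signed_rank_test",
    "rank_sum_test",
    "bh_adjust",
    "EXACT_N_MAX",
]

#: largest number of non-zero pairs for which the exact null distribution is used
EXACT_N_MAX = 25


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or paired location test."""

    statistic: float
    p_value: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _doubled_midranks(abs_diff: np.ndarray) -> np.ndarray:
    """Midranks of |d|, doubled so they are exact integers."""
    ranks = _sps.rankdata(abs_diff, method="average")
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    return doubled


def _exact_tail_probs(doubled_ranks: np.ndarray, w2: int) -> tuple[float, float]:
    """Return (P(W2 <= w2), P(W2 >= w2)) for the exact signed-rank null.

    ``W2`` is twice the sum of positive ranks. The count distribution is built
    by the standard shifted-convolution recurrence: each pair contributes its
    doubled rank to W2 or not, independently with probability 1/2.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    upper = 0
    for r in doubled_ranks:
        r = int(r)
        new = counts.copy()
        new[r : upper + r + 1] += counts[0 : upper + 1]
        counts = new
        upper += r
    denom = counts.sum()  # == 2**n, exact in floats for n <= 25
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return float(p_le), float(p_ge)


def signed_rank_test(diff: np.ndarray, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on a vector of paired differences.

    Parameters
    ----------
    diff
        Within-pair differences (e.g. per-feature CV in the comparison group
        minus the reference group). Zeros are dropped before ranking.
    mode
        ``"auto"`` (exact for <= 25 non-zero pairs, else normal approximation),
        ``"exact"`` or ``"approx"``.

    Returns
    -------
    TestResult with W+ (sum of positive midranks) as the statistic.
    """
    d = np.asarray(diff, dtype=float)
    if d.ndim != 1:
        raise ValueError("diff must be one-dimensional")
    if not np.all(np.isfinite(d)):
        raise ValueError("diff contains non-finite values")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn(
            "all paired differences are zero; p-value set to 1", UserWarning
        )
        return TestResult(statistic=0.0, p_value=1.0, n=0, method="signed-rank/degenerate")

    doubled = _doubled_midranks(np.abs(d))
    w_plus2 = int(doubled[d > 0].sum())

    if mode not in {"auto", "exact", "approx"}:
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_N_MAX)

    if use_exact:
        p_le, p_ge = _exact_tail_probs(doubled, w_plus2)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "signed-rank/exact"
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on original (undoubled) rank scale
        _, tie_counts = np.unique(doubled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            warnings.warn("degenerate rank variance; p-value set to 1", UserWarning)
            return TestResult(
                statistic=w_plus2 / 2.0, p_value=1.0, n=n, method="signed-rank/degenerate"
            )
        w_plus = w_plus2 / 2.0
        z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
        z = max(z, 0.0)
        p = min(1.0, 2.0 * float(_sps.norm.sf(z)))
        method = "signed-rank/normal"

    return TestResult(statistic=w_plus2 / 2.0, p_value=p, n=n, method=method)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test, for sensitivity use.

    This is the unpaired variant: it compares the two CV samples as
    independent groups instead of feature-wise pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = _sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(x.size + y.size),
        method="rank-sum/mannwhitney",
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    NaN entries (tests that could not be run) are passed through as NaN and do
    not count toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
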