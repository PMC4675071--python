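"""Per-feature coefficient of variation and the genome-wide variability
contrast between two phenotype groups.

The coefficient of variation CV = s / x-bar (sample SD with the n-1
denominator over the group's samples, divided by the group sample mean) is a
dimensionless, scale-invariant dispersion measure: multiplying every value of
a group by a positive constant leaves its CVs unchanged, so group-level
normalisation constants cancel out of the comparison.

The comparison itself is genome-wide: features are paired across the two
groups (each feature contributes one CV per group) and the paired CV
differences go into a two-sided Wilcoxon signed-rank test. The headline
effect measure is the change rate, the percent difference of mean CV in the
comparison group relative to the reference group. The unpaired rank-sum test
is available as a sensitivity option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io import ExpressionMatrix, SampleGroups
from .stats import rank_sum_test, signed_rank_test

__all__ = [
    "CVProfile",
    "VariabilityComparison",
    "feature_cv",
    "compare_cv",
    "change_rate_pct",
    "cv_density_summary",
]


@dataclass
class CVProfile:
    """Per-feature CV of one group's expression values."""

    group: str
    feature_ids: pd.Index
    cv: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.cv = np.asarray(self.cv, dtype=float)
        if self.cv.shape != (len(self.feature_ids),):
            raise ValueError("one CV per feature required")
        if not np.all(np.isfinite(self.cv)):
            raise ValueError("CV values must be finite")
        if np.any(self.cv < 0):
            raise ValueError("CV values must be non-negative")

    @property
    def mean_cv(self) -> float:
        return float(np.mean(self.cv))

    @property
    def sd_cv(self) -> float:
        return float(np.std(self.cv, ddof=1)) if self.cv.size > 1 else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature_id": self.feature_ids, "cv": self.cv})


@dataclass
class VariabilityComparison:
    """Genome-wide CV contrast between a reference and an alternative group.

    ``change_rate_pct`` is 100 * (mean_cv_alt - mean_cv_ref) / mean_cv_ref at
    full precision; display rounding to two decimals happens in the report
    layer.
    """

    ref_group: str
    alt_group: str
    mean_cv_ref: float
    sd_cv_ref: float
    mean_cv_alt: float
    sd_cv_alt: float
    change_rate_pct: float
    p_value: float
    n_features: int
    test_name: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def change_rate_pct(mean_cv_ref: float, mean_cv_alt: float) -> float:
    """Percent change of mean CV relative to the reference group."""
    if mean_cv_ref <= 0:
        raise ValueError("reference mean CV must be positive")
    return 100.0 * (mean_cv_alt - mean_cv_ref) / mean_cv_ref


def feature_cv(m: ExpressionMatrix, group: str, groups: SampleGroups) -> CVProfile:
    """Per-feature CV over one group's samples.

    Requires a linear-scale matrix (CV on log-scale values is a different,
    non-comparable quantity) with at least two samples in the group and a
    strictly positive group mean for every feature — run the validity filter
    first.
    """
    if m.scale != "linear":
        raise ValueError(
            "CV requires a linear-scale matrix; apply exprvar.io.unlog first"
        )
    groups.validate_against(m)
    samples = [s for s in groups.samples_in(group) if s in m.data.columns]
    if len(samples) < 2:
        raise ValueError(f"group {group!r} has {len(samples)} sample(s); need >= 2")
    sub = m.data[samples].to_numpy()
    if np.isnan(sub).any():
        raise ValueError("matrix contains missing values; filter features first")
    means = sub.mean(axis=1)
    if np.any(means <= 0):
        bad = m.feature_ids[means <= 0][0]
        raise ValueError(
            f"feature {bad!r} has non-positive mean in group {group!r}; "
            "filter features with group labels first"
        )
    sds = sub.std(axis=1, ddof=1)
    return CVProfile(group=group, feature_ids=m.feature_ids, cv=sds / means,
                     n_samples=len(samples))


def compare_cv(
    ref: CVProfile, alt: CVProfile, test: str = "signed-rank"
) -> VariabilityComparison:
    """Genome-wide comparison of per-feature CV between two groups.

    Features are matched by identity and order; the default test is the
    two-sided Wilcoxon signed-rank on per-feature differences
    (cv_alt - cv_ref), with the unpaired rank-sum test available via
    ``test="rank-sum"``.
    """
    if len(ref.feature_ids) != len(alt.feature_ids) or not np.array_equal(
        np.asarray(ref.feature_ids), np.asarray(alt.feature_ids)
    ):
        raise ValueError("profiles must share an identical, identically-ordered feature set")
    if ref.cv.size == 0:
        raise ValueError("empty CV profiles")

    diff = alt.cv - ref.cv
    if test == "signed-rank":
        if np.all(diff == 0.0):
            warnings.warn("all per-feature CV differences are zero", UserWarning)
        result = signed_rank_test(diff)
    elif test == "rank-sum":
        result = rank_sum_test(ref.cv, alt.cv)
    else:
        raise ValueError(f"unknown test {test!r}; use 'signed-rank' or 'rank-sum'")

    return VariabilityComparison(
        ref_group=ref.group,
        alt_group=alt.group,
        mean_cv_ref=ref.mean_cv,
        sd_cv_ref=ref.sd_cv,
        mean_cv_alt=alt.mean_cv,
        sd_cv_alt=alt.sd_cv,
        change_rate_pct=change_rate_pct(ref.mean_cv, alt.mean_cv),
        p_value=result.p_value,
        n_features=int(ref.cv.size),
        test_name=result.method,
    )


def cv_density_summary(
    profiles: list[CVProfile], grid: np.ndarray | None = None, n_grid: int = 512
) -> pd.DataFrame:
    """Gaussian KDE of each profile's CV values on a shared grid.

    Bandwidth follows Silverman's rule (a display convention; the density has
    no inferential role). Returns a tidy frame with columns ``group``, ``x``,
    ``density`` and ``group_mean`` (the per-group arithmetic mean CV, the
    quantity marked by vertical dashed lines in density plots).
    """
    if not profiles:
        raise ValueError("at least one profile required")
    for p in profiles:
        if np.unique(p.cv).size < 2:
            raise ValueError(
                f"profile {p.group!r} has fewer than 2 distinct CV values; "
                "density is degenerate"
            )
    if grid is None:
        lo = min(p.cv.min() for p in profiles)
        hi = max(p.cv.max() for p in profiles)
        span = hi - lo
        grid = np.linspace(lo - 0.1 * span, hi + 0.1 * span, n_grid)
    grid = np.asarray(grid, dtype=float)

    parts = []
    for p in profiles:
        kde = gaussian_kde(p.cv, bw_method="silverman")
        parts.append(
            pd.DataFrame(
                {
                    "group": p.group,
                    "x": grid,
                    "density": kde(grid),
                    "group_mean": p.mean_cv,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)
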