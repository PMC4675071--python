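"""qPCR relative quantification (comparative Ct, 2^-ddCt) and the paired
before/after-treatment panel analysis.

Quantification: dCt(s, g, t) = Ct(s, g, t) - Ct(s, ref, t) normalises each
gene to the reference gene (GAPDH in the emulated design) within the same
subject and timepoint; ddCt subtracts, per gene, the mean dCt of the
calibrator stratum (the baseline timepoint), and the relative quantity is
rq = 2^-ddCt. With this calibrator the baseline geometric-mean rq is 1 per
gene. The reference-only quantity 2^-dCt is also emitted, since published
per-gene expression levels are sometimes on that scale.

Panel analysis: per gene, a two-sided Wilcoxon signed-rank test on per-subject
(after - before) differences with fold change mean(after)/mean(before) and
Benjamini-Hochberg FDR across the panel; and, at the panel level, the per-gene
CV across subjects within each timepoint (genes play the role of features)
compared with the genome-wide CV machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CtTable
from .stats import bh_adjust, signed_rank_test
from .variability import CVProfile, VariabilityComparison, compare_cv

__all__ = [
    "RelativeExpression",
    "ddct_quantify",
    "paired_gene_tests",
    "panel_cv_comparison",
]


@dataclass
class RelativeExpression:
    """Relative quantities per (subject, gene, timepoint).

    ``data`` is long-format with columns subject_id, timepoint, gene,
    rel_to_ref (2^-dCt) and rq (2^-ddCt, calibrated to the baseline stratum).
    The reference gene is excluded.
    """

    data: pd.DataFrame
    ref_gene: str
    calibrator_timepoint: str

    def __post_init__(self) -> None:
        required = {"subject_id", "timepoint", "gene", "rel_to_ref", "rq"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing column(s): {sorted(missing)}")
        if (self.data["gene"] == self.ref_gene).any():
            raise ValueError("reference gene must be excluded from rq output")
        for col in ("rel_to_ref", "rq"):
            if (self.data[col] <= 0).any() or not np.isfinite(self.data[col]).all():
                raise ValueError(f"{col} must be positive and finite")

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def timepoints(self) -> list[str]:
        return sorted(self.data["timepoint"].unique())

    def wide(self, timepoint: str, value: str = "rq") -> pd.DataFrame:
        """Subject x gene table of one timepoint's quantities."""
        sub = self.data[self.data["timepoint"] == timepoint]
        return sub.pivot(index="subject_id", columns="gene", values=value)


def ddct_quantify(
    ct: CtTable, ref_gene: str, calibrator_timepoint: str
) -> RelativeExpression:
    """Comparative-Ct relative quantification of a Ct table.

    The calibrator is the per-gene mean dCt of ``calibrator_timepoint`` (the
    baseline stratum), so baseline rq values centre on 1. A missing reference
    Ct is a hard error naming the (subject, timepoint); a gene missing at one
    timepoint is simply absent from the output there (excluded pairwise
    downstream).
    """
    df = ct.data
    if calibrator_timepoint not in set(df["timepoint"]):
        raise ValueError(f"calibrator timepoint {calibrator_timepoint!r} not in table")
    ref = df[df["gene"] == ref_gene].set_index(["subject_id", "timepoint"])["ct"]
    strata = df[["subject_id", "timepoint"]].drop_duplicates()
    for subject, timepoint in strata.itertuples(index=False):
        if (subject, timepoint) not in ref.index:
            raise ValueError(
                f"reference gene {ref_gene!r} missing for subject {subject!r} "
                f"at timepoint {timepoint!r}"
            )

    target = df[df["gene"] != ref_gene].copy()
    if target.empty:
        raise ValueError("Ct table contains no target genes")
    ref_ct = ref.loc[list(zip(target["subject_id"], target["timepoint"]))].to_numpy()
    target["dct"] = target["ct"].to_numpy() - ref_ct

    base = target[target["timepoint"] == calibrator_timepoint]
    calibrator = base.groupby("gene")["dct"].mean()
    absent = sorted(set(target["gene"]) - set(calibrator.index))
    if absent:
        raise ValueError(f"gene(s) absent from calibrator stratum: {absent}")

    target["ddct"] = target["dct"] - calibrator.loc[target["gene"]].to_numpy()
    target["rel_to_ref"] = np.exp2(-target["dct"])
    target["rq"] = np.exp2(-target["ddct"])

    out = target[["subject_id", "timepoint", "gene", "rel_to_ref", "rq"]].reset_index(
        drop=True
    )
    return RelativeExpression(out, ref_gene=ref_gene,
                              calibrator_timepoint=calibrator_timepoint)


def paired_gene_tests(
    re: RelativeExpression,
    baseline: str,
    followup: str,
    value: str = "rq",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-gene paired before/after analysis of the panel.

    For each gene: mean +/- SD at both timepoints over complete pairs, fold
    change FC = mean(after) / mean(before), two-sided Wilcoxon signed-rank p
    on per-subject (after - before), and BH-FDR across the panel. Genes with
    fewer than ``min_pairs`` complete pairs get p = NaN with a warning.
    """
    before = re.wide(baseline, value)
    after = re.wide(followup, value)
    genes = sorted(set(before.columns) | set(after.columns))
    subjects = before.index.union(after.index)
    before = before.reindex(index=subjects, columns=genes)
    after = after.reindex(index=subjects, columns=genes)

    rows = []
    for gene in genes:
        pair_mask = before[gene].notna() & after[gene].notna()
        b = before.loc[pair_mask, gene].to_numpy()
        a = after.loc[pair_mask, gene].to_numpy()
        n = int(pair_mask.sum())
        if n < min_pairs:
            warnings.warn(
                f"gene {gene!r} has only {n} complete pair(s); p recorded missing",
                UserWarning,
            )
            p = np.nan
        else:
            p = signed_rank_test(a - b).p_value
        rows.append(
            {
                "gene": gene,
                "n_pairs": n,
                "mean_before": b.mean() if n else np.nan,
                "sd_before": b.std(ddof=1) if n > 1 else np.nan,
                "mean_after": a.mean() if n else np.nan,
                "sd_after": a.std(ddof=1) if n > 1 else np.nan,
                "fc": (a.mean() / b.mean()) if n and b.mean() > 0 else np.nan,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return table


def panel_cv_comparison(
    re: RelativeExpression,
    baseline: str,
    followup: str,
    value: str = "rq",
    test: str = "signed-rank",
) -> VariabilityComparison:
    """Panel-level contrast of per-gene expression CV before vs after.

    The per-gene CV is taken across subjects within each timepoint; the gene
    panel then plays the role of the feature set in the genome-wide
    comparison, with baseline as the reference group. Scale invariance of the
    CV makes the result identical for rq and rel_to_ref quantities.
    """
    profiles = {}
    for label in (baseline, followup):
        wide = re.wide(label, value).dropna(axis=1)
        if wide.shape[1] < 2 or wide.shape[0] < 2:
            raise ValueError(
                f"timepoint {label!r} needs >= 2 genes and >= 2 subjects "
                "with complete data"
            )
        means = wide.mean(axis=0)
        if (means <= 0).any():
            raise ValueError("non-positive gene mean encountered")
        cv = (wide.std(axis=0, ddof=1) / means).to_numpy()
        profiles[label] = CVProfile(
            group=label, feature_ids=wide.columns, cv=cv, n_samples=wide.shape[0]
        )
    if not profiles[baseline].feature_ids.equals(profiles[followup].feature_ids):
        common = profiles[baseline].feature_ids.intersection(
            profiles[followup].feature_ids
        )
        for label in (baseline, followup):
            keep = profiles[label].feature_ids.isin(common)
            profiles[label] = CVProfile(
                group=label,
                feature_ids=profiles[label].feature_ids[keep],
                cv=profiles[label].cv[keep],
                n_samples=profiles[label].n_samples,
            )
    return compare_cv(profiles[baseline], profiles[followup], test=test)
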