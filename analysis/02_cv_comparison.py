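#!/usr/bin/env python
"""Genome-wide CV comparison of the two simulated microarray datasets.

Reads the matrices written by 01_simulate_datasets.py, filters to valid
features, computes per-feature CV by group, and contrasts the groups with the
paired signed-rank test. Writes a two-row comparison table (one row per
platform), per-group CV profiles, the density-curve export and a density
figure. Expected outcome at the default inflation factors: a ~39% mean CV
increase for the mRNA-shaped data and ~14% for the miRNA-shaped data (the
latter attenuated below its generative 19.75% by finite-sample CV estimation
at CV ~ 0.8, n = 15), both with extreme significance.
"""

import argparse
from pathlib import Path

from exprvar.io import filter_valid_features, read_matrix, read_sample_groups
from exprvar.report import build_comparison_table, plot_cv_density, write_cv_profile
from exprvar.variability import compare_cv, cv_density_summary, feature_cv


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    comparisons, labels = [], []
    for preset in ("mrna", "mirna"):
        matrix = read_matrix(args.datadir / f"{preset}_matrix.tsv", "linear")
        groups = read_sample_groups(args.datadir / f"{preset}_meta.tsv")
        matrix, report = filter_valid_features(matrix, groups)
        print(f"{preset}: {report.n_retained}/{report.n_input} valid features")

        ref = feature_cv(matrix, "control", groups)
        alt = feature_cv(matrix, "case", groups)
        for prof in (ref, alt):
            write_cv_profile(prof, args.outdir / f"{preset}_cv_{prof.group}.tsv")

        comparison = compare_cv(ref, alt)
        comparisons.append(comparison)
        labels.append(preset)
        print(
            f"{preset}: mean CV {comparison.mean_cv_ref:.3f} (control) -> "
            f"{comparison.mean_cv_alt:.3f} (case), change "
            f"{comparison.change_rate_pct:+.2f}%, p = {comparison.p_value:.3g}"
        )

        density = cv_density_summary([ref, alt])
        density.to_csv(args.outdir / f"{preset}_cv_density.tsv", sep="\t", index=False)
        plot_cv_density(density, args.outdir / f"{preset}_cv_density.png")

    table = build_comparison_table(comparisons, labels)
    table.to_csv(args.outdir / "cv_comparison_table.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
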