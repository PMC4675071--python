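import numpy as np
import pandas as pd
import pytest

from exprvar.qpcr import ddct_quantify, panel_cv_comparison
from exprvar.synthetic import (
    DEFAULT_QPCR_PANEL,
    QpcrSpec,
    SyntheticSpec,
    _lognormal_draws,
    generate_matrix,
    generate_qpcr,
    matrix_preset,
    qpcr_preset,
)
from exprvar.variability import compare_cv, feature_cv


def run_comparison(spec):
    m, groups, _ = generate_matrix(spec)
    ref = feature_cv(m, spec.ref_label, groups)
    alt = feature_cv(m, spec.alt_label, groups)
    return compare_cv(ref, alt)


class TestDeterminism:
    def test_identical_spec_bit_identical_matrix(self):
        spec = SyntheticSpec(
            n_features=50, n_ref=5, n_alt=6, cv_mean=0.3, cv_sd=0.1,
            missing_rate=0.05, seed=123,
        )
        m1, g1, t1 = generate_matrix(spec)
        m2, g2, t2 = generate_matrix(spec)
        pd.testing.assert_frame_equal(m1.data, m2.data)
        assert g1.assignment == g2.assignment
        pd.testing.assert_frame_equal(t1, t2)

    def test_identical_spec_bit_identical_ct(self):
        spec = QpcrSpec(seed=321)
        ct1, truth1, _ = generate_qpcr(spec)
        ct2, truth2, _ = generate_qpcr(spec)
        pd.testing.assert_frame_equal(ct1.data, ct2.data)
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_yaml_round_trip(self, tmp_path):
        spec = matrix_preset("mirna", seed=9)
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        assert SyntheticSpec.from_yaml(path) == spec


class TestCvLaw:
    def test_lognormal_hits_target_cv_at_large_n(self):
        rng = np.random.default_rng(0)
        draws = _lognormal_draws(rng, np.array([100.0]), np.array([0.5]), 10000)
        sample_cv = draws.std(ddof=1) / draws.mean()
        assert abs(sample_cv - 0.5) < 0.02

    def test_gamma_cvs_positive_and_truncated(self):
        spec = SyntheticSpec(
            n_features=5000, n_ref=2, n_alt=2, cv_mean=0.81, cv_sd=0.41,
            cv_max=1.5, seed=4,
        )
        _, _, truth = generate_matrix(spec)
        assert (truth["cv_ref"] > 0).all()
        assert (truth["cv_ref"] < 1.5).all()

    def test_gamma_cvs_match_moments_when_truncation_negligible(self):
        spec = SyntheticSpec(
            n_features=5000, n_ref=2, n_alt=2, cv_mean=0.81, cv_sd=0.41, seed=4,
        )
        _, _, truth = generate_matrix(spec)
        assert truth["cv_ref"].mean() == pytest.approx(0.81, abs=0.03)
        assert truth["cv_ref"].std(ddof=1) == pytest.approx(0.41, abs=0.03)

    def test_truncated_gaussian_warns_at_large_cv(self):
        spec = SyntheticSpec(
            n_features=20, n_ref=5, n_alt=5, cv_mean=0.8, cv_sd=0.2,
            noise_family="truncated_gaussian", seed=5,
        )
        with pytest.warns(UserWarning, match="truncation|negative"):
            m, _, _ = generate_matrix(spec)
        assert (m.values > 0).all()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_features=0, n_ref=3, n_alt=3, cv_mean=0.1, cv_sd=0.1, seed=1)
        with pytest.raises(ValueError):
            SyntheticSpec(
                n_features=5, n_ref=3, n_alt=3, cv_mean=0.1, cv_sd=0.1,
                missing_rate=1.0, seed=1,
            )
        with pytest.raises(ValueError):
            QpcrSpec(seed=1, deflation=0.0)


class TestNullCalibration:
    def test_equal_group_sizes_rejection_near_alpha(self):
        """With exchangeable groups (kappa=1, equal n) the genome-wide paired
        signed-rank p-value is approximately uniform: rejection at alpha=0.05
        over 400 seeded replicates stays inside a 3-sigma binomial band."""
        rejections = 0
        n_seeds = 400
        for seed in range(n_seeds):
            spec = SyntheticSpec(
                n_features=500, n_ref=15, n_alt=15, cv_mean=0.062, cv_sd=0.043,
                seed=seed,
            )
            rejections += run_comparison(spec).p_value < 0.05
        assert 0.02 <= rejections / n_seeds <= 0.085

    def test_unequal_group_sizes_bias_direction(self):
        """With n_alt > n_ref and kappa=1 the sample-CV estimator's
        n-dependence produces a small positive spurious change rate (the
        larger group's CVs are less attenuated)."""
        changes = [
            run_comparison(
                SyntheticSpec(
                    n_features=2000, n_ref=12, n_alt=18, cv_mean=0.062,
                    cv_sd=0.043, seed=seed,
                )
            ).change_rate_pct
            for seed in range(40)
        ]
        assert 0.0 < np.mean(changes) < 2.0


class TestRecovery:
    @pytest.mark.parametrize("kappa", [1.2, 1.4])
    def test_change_rate_recovers_inflation(self, kappa):
        """At mRNA-scale CVs and group sizes the mean estimated change rate
        over seeds is within 3 points of 100*(kappa-1)."""
        changes = [
            run_comparison(
                SyntheticSpec(
                    n_features=2000, n_ref=12, n_alt=18, cv_mean=0.062,
                    cv_sd=0.043, inflation_kappa=kappa, seed=seed,
                )
            ).change_rate_pct
            for seed in range(30)
        ]
        assert abs(np.mean(changes) - 100.0 * (kappa - 1.0)) < 3.0

    def test_exact_cv_mode_recovers_inflation_exactly(self):
        """With sample moments imposed exactly, the measured change rate is
        100*(kappa-1) to numerical precision, per the convergence identity."""
        spec = SyntheticSpec(
            n_features=300, n_ref=12, n_alt=18, cv_mean=0.81, cv_sd=0.41,
            inflation_kappa=1.1975, exact_cv=True, seed=11,
        )
        comp = run_comparison(spec)
        assert comp.change_rate_pct == pytest.approx(19.75, abs=1e-9)

    def test_mean_shift_leaves_cv_comparison_unchanged(self):
        """A multiplicative group mean shift (the down-regulated small-RNA
        case) moves the expression contrast but not the CV comparison."""
        base = matrix_preset("mirna", seed=3, n_features=400, mean_shift=1.0)
        shifted = matrix_preset("mirna", seed=3, n_features=400, mean_shift=0.6)
        c1, c2 = run_comparison(base), run_comparison(shifted)
        assert c1.change_rate_pct == pytest.approx(c2.change_rate_pct, rel=1e-12)
        assert c1.p_value == c2.p_value

        m1, g1, _ = generate_matrix(base)
        m2, _, _ = generate_matrix(shifted)
        alt_samples = g1.samples_in(shifted.alt_label)
        ratio = m2.data[alt_samples].mean().mean() / m1.data[alt_samples].mean().mean()
        assert ratio == pytest.approx(0.6, rel=1e-12)


class TestQpcrGenerator:
    def test_presets_have_study_shapes(self):
        mrna = matrix_preset("mrna", seed=1)
        assert (mrna.n_features, mrna.n_ref, mrna.n_alt) == (17199, 12, 18)
        mirna = matrix_preset("mirna", seed=1)
        assert (mirna.n_features, mirna.n_ref, mirna.n_alt) == (2967, 15, 15)
        qspec = qpcr_preset(seed=1)
        assert len(qspec.panel) == 17
        assert qspec.n_subjects == 30
        implied_cvs = [sd / mean for mean, sd in DEFAULT_QPCR_PANEL.values()]
        assert np.mean(implied_cvs) == pytest.approx(0.81, abs=0.02)
        assert np.std(implied_cvs, ddof=1) == pytest.approx(0.52, abs=0.03)

    def test_ct_round_trip_recovers_generated_rq(self):
        """Quantifying the emitted Ct table recovers the generator's
        calibrated relative quantities to floating-point accuracy."""
        spec = QpcrSpec(seed=42)
        ct, truth, _ = generate_qpcr(spec)
        re_ = ddct_quantify(ct, spec.ref_gene, spec.baseline_label)
        merged = re_.data.merge(truth, on=["subject_id", "timepoint", "gene"])
        assert len(merged) == len(truth)
        assert np.allclose(merged["rq"], merged["rq_calibrated"], rtol=1e-9)

    def test_reference_gene_present_everywhere_ct_positive(self):
        spec = QpcrSpec(seed=2)
        ct, _, _ = generate_qpcr(spec)
        ref_rows = ct.data[ct.data.gene == spec.ref_gene]
        assert len(ref_rows) == spec.n_subjects * 2
        assert (ct.data["ct"] > 0).all()

    def test_unit_deflation_change_rate_centered_at_zero(self):
        changes = []
        for seed in range(40):
            spec = QpcrSpec(seed=seed, deflation=1.0)
            ct, _, _ = generate_qpcr(spec)
            re_ = ddct_quantify(ct, spec.ref_gene, spec.baseline_label)
            changes.append(panel_cv_comparison(re_, "0W", "12W").change_rate_pct)
        assert abs(np.mean(changes)) < 4.0

    def test_means_preserved_under_deflation(self):
        spec = QpcrSpec(seed=8, deflation=0.7)
        _, truth, params = generate_qpcr(spec)
        wide = truth.pivot_table(
            index="gene", columns="timepoint", values="expression", aggfunc="mean"
        )
        target = params.set_index("gene")["mean"]
        # per-gene empirical means at both timepoints track the same target
        for tp in (spec.baseline_label, spec.followup_label):
            rel_err = (wide[tp] - target).abs() / target
            assert rel_err.median() < 0.25
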