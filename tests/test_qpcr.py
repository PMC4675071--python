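import numpy as np
import pandas as pd
import pytest

from exprvar.io import CtTable
from exprvar.qpcr import ddct_quantify, paired_gene_tests, panel_cv_comparison
from exprvar.synthetic import QpcrSpec, generate_qpcr

from .conftest import make_ct_table
from .oracles import enumerate_signed_rank_p


def rq_of(re_, subject, timepoint, gene):
    sub = re_.data
    row = sub[
        (sub.subject_id == subject) & (sub.timepoint == timepoint) & (sub.gene == gene)
    ]
    return float(row["rq"].iloc[0])


class TestDdctQuantify:
    def test_rq_one_when_dct_equals_calibrator_mean(self, paired_ct):
        re_ = ddct_quantify(paired_ct, "REF", "0W")
        # geneX has identical baseline dCt (=2) for both subjects => rq = 1
        assert rq_of(re_, "S1", "0W", "geneX") == pytest.approx(1.0, abs=1e-12)
        assert rq_of(re_, "S2", "0W", "geneX") == pytest.approx(1.0, abs=1e-12)

    def test_one_cycle_drop_doubles_quantity(self, paired_ct):
        # geneX follow-up dCt = 1 vs calibrator mean 2 => ddCt = -1 => rq = 2
        re_ = ddct_quantify(paired_ct, "REF", "0W")
        assert rq_of(re_, "S1", "12W", "geneX") == pytest.approx(2.0, abs=1e-12)

    def test_ddct_closed_form_tenth(self):
        # ddCt = 3.3219 corresponds to rq = 2^-3.3219 ~ 0.1000
        ct = make_ct_table(
            {
                ("S1", "0W", "REF"): 20.0,
                ("S1", "0W", "g"): 22.0,
                ("S2", "0W", "REF"): 20.0,
                ("S2", "0W", "g"): 22.0,
                ("S1", "12W", "REF"): 20.0,
                ("S1", "12W", "g"): 22.0 + 3.3219,
                ("S2", "12W", "REF"): 20.0,
                ("S2", "12W", "g"): 22.0 + 3.3219,
            }
        )
        re_ = ddct_quantify(ct, "REF", "0W")
        assert rq_of(re_, "S1", "12W", "g") == pytest.approx(0.1000, abs=1e-4)

    def test_stratum_shift_invariance(self, paired_ct):
        """Adding a constant to all Ct values of one (subject, timepoint)
        stratum cancels in the reference subtraction."""
        base = ddct_quantify(paired_ct, "REF", "0W")
        shifted = paired_ct.data.copy()
        stratum = (shifted.subject_id == "S1") & (shifted.timepoint == "12W")
        shifted.loc[stratum, "ct"] += 4.25
        out = ddct_quantify(CtTable(shifted), "REF", "0W")
        pd.testing.assert_frame_equal(base.data, out.data)

    def test_missing_reference_names_stratum(self, paired_ct):
        broken = paired_ct.data[
            ~(
                (paired_ct.data.subject_id == "S2")
                & (paired_ct.data.timepoint == "12W")
                & (paired_ct.data.gene == "REF")
            )
        ]
        with pytest.raises(ValueError, match="S2.*12W"):
            ddct_quantify(CtTable(broken), "REF", "0W")

    def test_reference_gene_excluded_and_rq_positive(self, paired_ct):
        re_ = ddct_quantify(paired_ct, "REF", "0W")
        assert "REF" not in set(re_.data.gene)
        assert (re_.data["rq"] > 0).all()
        assert (re_.data["rel_to_ref"] > 0).all()


class TestPairedGeneTests:
    def test_identical_timepoints_null_table(self):
        values = {}
        for s, noise in (("S1", 0.3), ("S2", -0.2), ("S3", 0.1), ("S4", 0.0)):
            for t in ("0W", "12W"):
                values[(s, t, "REF")] = 20.0
                values[(s, t, "gA")] = 23.0 + noise
                values[(s, t, "gB")] = 25.0 - noise
        re_ = ddct_quantify(make_ct_table(values), "REF", "0W")
        with pytest.warns(UserWarning):
            table = paired_gene_tests(re_, "0W", "12W")
        assert np.allclose(table["p"], 1.0)
        assert np.allclose(table["fc"], 1.0)

    def test_doubled_expression_gives_fc_two(self):
        values = {}
        for i, base in enumerate((22.0, 23.5, 24.0, 21.0)):
            s = f"S{i}"
            values[(s, "0W", "REF")] = 20.0
            values[(s, "12W", "REF")] = 20.0
            values[(s, "0W", "gA")] = base
            values[(s, "12W", "gA")] = base - 1.0  # one cycle less = doubled
        re_ = ddct_quantify(make_ct_table(values), "REF", "0W")
        table = paired_gene_tests(re_, "0W", "12W")
        assert table.loc[table.gene == "gA", "fc"].iloc[0] == pytest.approx(2.0, rel=1e-12)

    def test_too_few_pairs_warns_and_records_nan(self, paired_ct):
        re_ = ddct_quantify(paired_ct, "REF", "0W")
        with pytest.warns(UserWarning, match="complete pair"):
            table = paired_gene_tests(re_, "0W", "12W", min_pairs=3)
        assert table["p"].isna().all()

    def test_p_matches_enumeration_oracle_small_n(self):
        spec = QpcrSpec(seed=5, n_subjects=8, deflation=0.9)
        ct, _, _ = generate_qpcr(spec)
        re_ = ddct_quantify(ct, spec.ref_gene, spec.baseline_label)
        table = paired_gene_tests(re_, spec.baseline_label, spec.followup_label)
        before = re_.wide(spec.baseline_label)
        after = re_.wide(spec.followup_label)
        for gene in table.gene.head(5):
            d = (after[gene] - before[gene]).to_numpy()
            expected = enumerate_signed_rank_p(d)
            got = table.loc[table.gene == gene, "p"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_fdr_at_least_raw_p(self):
        spec = QpcrSpec(seed=6)
        ct, _, _ = generate_qpcr(spec)
        re_ = ddct_quantify(ct, spec.ref_gene, spec.baseline_label)
        table = paired_gene_tests(re_, spec.baseline_label, spec.followup_label)
        assert (table["fdr"] >= table["p"] - 1e-15).all()


class TestPanelCVComparison:
    def test_identity_timepoints_zero_change(self):
        values = {}
        rng = np.random.default_rng(9)
        cts = rng.normal(24, 2, size=(4, 3))
        for i in range(4):
            for t in ("0W", "12W"):
                values[(f"S{i}", t, "REF")] = 20.0
                for j in range(3):
                    values[(f"S{i}", t, f"g{j}")] = cts[i, j]
        re_ = ddct_quantify(make_ct_table(values), "REF", "0W")
        with pytest.warns(UserWarning, match="zero"):
            comp = panel_cv_comparison(re_, "0W", "12W")
        assert comp.change_rate_pct == 0.0
        assert comp.p_value == 1.0

    def test_scale_choice_invariance(self):
        """CV is invariant to per-gene rescaling, so the panel comparison is
        identical whether built on rq (2^-ddCt) or rel_to_ref (2^-dCt)."""
        spec = QpcrSpec(seed=10)
        ct, _, _ = generate_qpcr(spec)
        re_ = ddct_quantify(ct, spec.ref_gene, spec.baseline_label)
        a = panel_cv_comparison(re_, "0W", "12W", value="rq")
        b = panel_cv_comparison(re_, "0W", "12W", value="rel_to_ref")
        assert a.change_rate_pct == pytest.approx(b.change_rate_pct, rel=1e-9)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_deflation_monte_carlo_change_rate(self):
        """Follow-up CV deflated by 0.84 over a fixed seed set: the mean
        estimated panel change rate lands in the expected band around -16%
        (finite-sample CV attenuation pulls it toward -13)."""
        changes = []
        for seed in range(60):
            spec = QpcrSpec(seed=seed, deflation=0.84)
            ct, _, _ = generate_qpcr(spec)
            re_ = ddct_quantify(ct, spec.ref_gene, spec.baseline_label)
            changes.append(panel_cv_comparison(re_, "0W", "12W").change_rate_pct)
        assert -19.0 < np.mean(changes) < -13.0

    def test_dissociation_panel_significant_genes_not(self):
        """CV deflation with means preserved: the panel-level test detects the
        variability decrease while per-gene paired tests stay null."""
        panel_hits = 0
        clean_gene_seeds = 0
        n_seeds = 40
        for seed in range(n_seeds):
            spec = QpcrSpec(seed=seed, deflation=0.84)
            ct, _, _ = generate_qpcr(spec)
            re_ = ddct_quantify(ct, spec.ref_gene, spec.baseline_label)
            comp = panel_cv_comparison(re_, "0W", "12W")
            genes = paired_gene_tests(re_, "0W", "12W")
            panel_hits += comp.p_value < 0.05
            clean_gene_seeds += bool((genes["fdr"] >= 0.05).all())
        assert panel_hits / n_seeds > 0.6
        assert clean_gene_seeds / n_seeds > 0.7
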