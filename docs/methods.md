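# Methods

## Model and procedure

The analysis treats a feature-by-sample expression matrix of positive,
linear-scale intensities as the unit of input. Per feature and group, the
coefficient of variation CV = s / x̄ uses the n−1 sample standard deviation;
group sizes of 12–30 make the n−1 vs n distinction material, and the sample
SD is the field's default. CV is only meaningful on linear intensities
(CV of log2 values is a different quantity with a different scale), so a
log2-flagged matrix must be passed through `unlog` first and the CLI refuses
to compute CV on one without an explicit flag.

Validity filtering precedes everything: a feature is dropped if it has any
missing value in a retained sample, or (when group labels are available) a
non-positive mean in any group, where CV is undefined. Nothing is imputed;
the dropped counts are reported. The filter is idempotent.

The genome-wide contrast pairs features across groups — each feature
contributes (CV_ref, CV_alt) — and applies the two-sided Wilcoxon signed-rank
test to the differences. "Paired" here refers to feature-wise pairing: with
unequal numbers of subjects per group there is no sample-level pairing
available. The unpaired rank-sum (Mann–Whitney) test on the two CV samples is
exposed as a sensitivity option. The effect summary is the change rate,
100 × (mean CV_alt − mean CV_ref) / mean CV_ref, stored at full precision and
displayed to two decimals.

### Signed-rank convention

Zero differences are dropped before ranking (Wilcoxon's original treatment);
tied absolute differences receive midranks. For ≤ 25 non-zero pairs the
p-value comes from the exact conditional null distribution of W⁺ given the
observed midranks, computed by shifted-convolution dynamic programming over
doubled (hence integer) ranks; the two-sided p is 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))
capped at 1. Beyond 25 pairs a normal approximation is used with the standard
tie correction Σ(t³−t)/48 on the variance and a 0.5 continuity correction.
The exact path is validated in the test suite against an independent
exhaustive enumeration of all 2ⁿ sign assignments, and the approximate path
against scipy's implementation.

### qPCR quantification

The comparative-Ct method: ΔCt(s,g,t) = Ct(s,g,t) − Ct(s,ref,t) with GAPDH as
the default reference; ΔΔCt subtracts the per-gene mean ΔCt of the baseline
(calibrator) stratum, chosen so baseline relative quantities centre on 1 —
the conventional presentation. Because published per-gene expression levels
are sometimes reported normalised to the reference gene only, the
reference-only quantity 2^−ΔCt is emitted alongside the calibrated 2^−ΔΔCt
and either can drive the per-gene summaries; the panel-level CV comparison is
provably identical under the two choices (CV is invariant to per-gene
constants), as is the per-gene signed-rank p (per-gene scaling preserves
difference ranks). Fold change is defined as mean(after)/mean(before). The
per-gene test is the signed-rank (robust at n = 30 and consistent with the
panel-level test); FDR is Benjamini–Hochberg step-up across the panel. Genes
with fewer than 3 complete pairs get a missing p with a warning. No
amplification-efficiency correction (Pfaffl) or standard curves: plain
2^−ΔΔCt is the target of this package.

## Synthetic-data generators

The generators exist to give every stage a testbed with known ground truth;
they are the package's modelling assumptions, not a claim about how real
microarray data arise.

**Case/control matrices.** Per feature, a baseline mean is drawn log-normally
(default log-mean ln 300, log-SD 1 — a typical intensity spread) and a
baseline CV from a gamma law moment-matched to a target (mean, SD), truncated
at cv_max = 3 by resampling (truncation is negligible at both presets).
Reference samples are drawn log-normally with that mean and CV (exact, via
σ² = ln(1+CV²)); the alternative group's CV is multiplied by an inflation
factor κ and its mean by an optional shift (down-regulation when < 1, with
no effect on CV). A zero-truncated-Gaussian noise family is included as a
robustness stress test; its realised CV is biased once CV exceeds ~0.43
(> 1% of mass below zero), and it warns accordingly. Missing cells are
injected uniformly at a configurable rate. Two presets encode the target
study shapes: 17199 features with 12 vs 18 samples and CV ~ gamma(0.062,
0.043), inflation 0.086/0.062; and 2967 features with 15 vs 15, CV ~
gamma(0.81, 0.41), inflation 0.97/0.81, mean shift 0.8 (the down-regulated
small-RNA case; the shift magnitude is a package choice, since only the
direction is anchored, and the CV analysis is invariant to it).

An `exact_cv` mode affinely rescales each feature's group samples to the
target sample mean and sample CV exactly, making the measured change rate
equal 100(κ−1) identically — useful for separating estimator effects from
generator effects. At large CV the affine map can push individual values
below zero (background-subtracted-intensity behaviour); group means stay
positive.

**Paired qPCR panels.** 17 genes × 30 subjects by default. The per-gene
baseline means and SDs default to a fixed panel profile whose implied
per-gene CVs average 0.80 (SD 0.52), the regime the panel analysis targets.
Follow-up values share the subject's log-scale component with weight
ρ = 0.8 — repeated measures on the same subjects are substantially
correlated, and 0.8 is a defensible test-retest stability for blood
expression — with per-gene CV multiplied by a deflation factor (default
0.68/0.81 ≈ 0.84) and a mean-preserving location adjustment, so the panel's
variability shrinks while per-gene expectations are unchanged. The panel is
emitted as a Ct table by inverting the comparative-Ct map through a synthetic
GAPDH whose Ct is the stratum level (N(20, 0.15²)); quantifying that table
recovers the generator's calibrated relative quantities to ~1e-12, which the
suite asserts at 1e-9.

Seeds are mandatory; identical spec ⇒ bit-identical output. What the
generators do *not* emulate: probe-level physics, background correction,
batch and array effects, clinical covariates, within-group biological
subtypes, and feature–feature correlation (features are independent given
the spec). Passing tests therefore demonstrate correctness of the statistics
under a clean generative model, not robustness to real-data artefacts.

## Operating characteristics and known limitations

**Null calibration depends on balanced groups.** The sample CV is biased
downward in small samples (for near-Gaussian data E[s] = σ·c₄(n), c₄(12) ≈
0.977, c₄(18) ≈ 0.985). With equal group sizes the bias cancels in the
feature-wise pairing and the genome-wide test is calibrated (measured
rejection 0.050 at α = 0.05 over 400 replicates, 15 vs 15). With unequal
sizes it does not cancel: every feature's CV difference acquires the same
small positive offset (~0.8% of CV for 12 vs 18), and because the
genome-wide test aggregates thousands of features, this tiny per-feature
shift produces rejection rates near 0.34 at 2000 features under a true null
— and would grow with feature count. Consequence: for unbalanced designs the
genome-wide paired CV test is anti-conservative, and extreme p-values from
such designs should not be read at face value. A CV comparison between
groups of unequal size should either subsample to balance, use a bias-
corrected CV estimator, or calibrate by permutation; these are deliberately
out of scope here, where the plain estimator is the object of study.

**Change-rate attenuation at large CV.** The measured change rate recovers
100(κ−1) well when CVs are small (mRNA preset: mean estimate 39.7% vs
generative 38.71%, slightly above because of the group-size bias just
described). At CV ~ 0.8 with 15 samples, the CV estimator is nonlinearly
attenuated (heavier attenuation at larger CV), so inflating true CVs by
κ = 1.1975 yields a measured mean change of ~14.3%, not 19.75%. The exact_cv
mode confirms the discrepancy is purely an estimation effect. The same
attenuation moves the qPCR panel's measured change rate to ~ −13% under a
generative deflation of 0.84 (which would correspond to −16% on true CVs).
Printed change rates computed from *measured* CV summaries are therefore not
directly comparable with generative inflation factors in the large-CV
regime.

**Panel power is boundary-line at the default effect.** At deflation 0.84,
ρ = 0.8, 17 genes × 30 subjects, the panel-level exact signed-rank test
detects the CV decrease in ~78% of replicates at α = 0.05, while no gene
reaches FDR < 0.05 in ~90% of replicates — the dissociation (collective
variability change, no per-gene expression change) reproduces robustly, but
its power sits near 0.8 and is sensitive to the assumed within-subject
stability ρ (power rises quickly toward ρ = 1 because correlated sampling
error cancels in the paired CV differences).

## Numerical and formatting choices

Exact signed-rank switches to the normal approximation above 25 non-zero
pairs (exact DP cost is negligible there, but the convention is fixed for
reproducibility and matches common practice). KDE for density exports uses
Gaussian kernels with Silverman's bandwidth — a display choice with no
inferential role; densities are checked to integrate to 1 within 0.01.
Mean ± SD strings print 3 decimals below 0.1 and 2 decimals at or above 0.1,
matching the mixed precision of compact CV tables; p-values display in
scientific notation floored at "<1.00E-30" while stored values keep full
precision. Result tables carry the config hash of the run that produced
them; runs are byte-reproducible from their persisted YAML config because no
output depends on wall-clock time.
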