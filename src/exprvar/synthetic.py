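"""Seeded synthetic-data generators with the statistical structure the
analysis assumes.

Two generators are provided:

* :func:`generate_matrix` — microarray-like case/control expression matrices.
  Per feature, a baseline mean is drawn log-normally and a baseline CV from a
  gamma law moment-matched to a target (mean, SD) and truncated at ``cv_max``.
  Reference-group samples are drawn with that mean and CV; the alternative
  group's CV is multiplied by an inflation factor kappa (the simulated analog
  of stochastic deregulation of genome expression) and its mean by an
  optional shift (down-regulation when < 1). For the log-normal noise family
  the target CV is hit exactly through sigma = sqrt(ln(1 + cv^2)); the
  truncated-Gaussian family is a robustness stress test whose realised CV is
  biased once truncation at zero removes appreciable mass.

* :func:`generate_qpcr` — a paired before/after qPCR panel (by default 17
  genes x 30 subjects). Per-gene baseline means and SDs default to a profile
  whose per-gene CVs average ~0.81; at follow-up each gene's CV is multiplied
  by a deflation factor while its mean is preserved, so the panel shows a CV
  decrease without per-gene expression changes. Baseline and follow-up share
  a per-subject log-scale component (within-subject stability rho), as
  repeated measures on the same subjects do. The panel can be emitted as Ct
  values through a synthetic reference gene by inverting the comparative-Ct
  map.

All randomness flows from the mandatory integer seed; identical spec =>
bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm, truncnorm

from .io import CtTable, ExpressionMatrix, SampleGroups

__all__ = [
    "SyntheticSpec",
    "QpcrSpec",
    "generate_matrix",
    "generate_qpcr",
    "matrix_preset",
    "qpcr_preset",
    "DEFAULT_QPCR_PANEL",
]

# Synthetic 17-gene qPCR panel profile: per-gene baseline mean and SD of
# relative expression (reference-normalised scale). The per-gene CVs implied
# by these pairs average ~0.80 with SD ~0.52, the regime the panel analysis
# is designed for.
DEFAULT_QPCR_PANEL: dict[str, tuple[float, float]] = {
    "AKT1": (0.076, 0.022),
    "BRCA1": (6.57e-3, 2.79e-3),
    "CCDC134": (0.012, 0.026),
    "FAHH": (4.84e-3, 2.25e-3),
    "FOS": (1.09, 0.55),
    "HTR4": (1.70e-4, 9.44e-5),
    "JUN": (4.49e-3, 3.60e-3),
    "MYOD1": (2.22e-3, 3.00e-3),
    "NKAPL": (3.40e-3, 2.20e-3),
    "RGS2": (0.75, 0.43),
    "STAT3": (0.049, 0.031),
    "UBD": (3.82e-3, 4.70e-3),
    "VDR": (0.010, 4.81e-3),
    "ZIC2": (3.97e-3, 6.36e-3),
    "EGR1": (0.19, 0.21),
    "SKIL": (5.28e-3, 2.02e-3),
    "NFKB": (0.026, 0.012),
}


@dataclass
class SyntheticSpec:
    """Generative parameters for a case/control expression matrix.

    cv_mean / cv_sd parameterise the gamma law of per-feature baseline CVs;
    inflation_kappa multiplies the alternative group's CV; mean_shift
    multiplies its mean (no effect on CV). mu_log_mean / mu_log_sd are the
    log-scale parameters of the per-feature baseline-mean law.
    """

    n_features: int
    n_ref: int
    n_alt: int
    cv_mean: float
    cv_sd: float
    seed: int
    inflation_kappa: float = 1.0
    mean_shift: float = 1.0
    missing_rate: float = 0.0
    noise_family: str = "lognormal"
    cv_max: float = 3.0
    mu_log_mean: float = math.log(300.0)
    mu_log_sd: float = 1.0
    exact_cv: bool = False
    ref_label: str = "control"
    alt_label: str = "case"

    def __post_init__(self) -> None:
        for name in ("n_features", "n_ref", "n_alt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cv_mean", "cv_sd", "inflation_kappa", "mean_shift", "cv_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_family not in {"lognormal", "truncated_gaussian"}:
            raise ValueError(f"unknown noise_family {self.noise_family!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class QpcrSpec:
    """Generative parameters for a paired before/after qPCR panel.

    ``panel`` maps gene -> (baseline mean, baseline SD) of relative
    expression; ``deflation`` multiplies every gene's CV at follow-up while
    preserving its mean; ``rho`` is the within-subject log-scale correlation
    between the two timepoints (test-retest stability of expression).
    """

    seed: int
    panel: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_QPCR_PANEL)
    )
    n_subjects: int = 30
    deflation: float = 0.68 / 0.81
    rho: float = 0.8
    ref_gene: str = "GAPDH"
    ref_ct_mean: float = 20.0
    ref_ct_sd: float = 0.15
    baseline_label: str = "0W"
    followup_label: str = "12W"

    def __post_init__(self) -> None:
        if self.deflation <= 0:
            raise ValueError("deflation factor must be positive")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must be in (-1, 1)")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        for gene, (mean, sd) in self.panel.items():
            if mean <= 0 or sd <= 0:
                raise ValueError(f"gene {gene!r} needs positive mean and SD")
        if self.ref_gene in self.panel:
            raise ValueError("reference gene cannot be part of the target panel")


def _draw_truncated_gamma_cvs(
    rng: np.random.Generator, n: int, mean: float, sd: float, cv_max: float
) -> np.ndarray:
    """Gamma(mean, sd)-matched baseline CVs, resampled above cv_max."""
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    cvs = rng.gamma(shape, scale, size=n)
    for _ in range(1000):
        bad = cvs >= cv_max
        if not bad.any():
            break
        cvs[bad] = rng.gamma(shape, scale, size=int(bad.sum()))
    else:
        raise ValueError("cv_law mass almost entirely above cv_max; lower cv_mean/cv_sd")
    if np.any(cvs <= 0):
        raise ValueError("cv_law produced non-positive CVs")
    return cvs


def _lognormal_draws(
    rng: np.random.Generator, means: np.ndarray, cvs: np.ndarray, n_samples: int
) -> np.ndarray:
    """(features x samples) log-normal draws hitting each mean/CV exactly."""
    sigma2 = np.log1p(cvs**2)
    mu = np.log(means) - sigma2 / 2.0
    z = rng.standard_normal((means.size, n_samples))
    return np.exp(mu[:, None] + np.sqrt(sigma2)[:, None] * z)


def _truncated_gaussian_draws(
    rng: np.random.Generator, means: np.ndarray, cvs: np.ndarray, n_samples: int
) -> np.ndarray:
    """Zero-truncated Gaussian draws with nominal mean/CV (biased by truncation)."""
    frac_negative = norm.cdf(-1.0 / cvs)
    if np.any(frac_negative > 0.01):
        warnings.warn(
            "truncated_gaussian family: >1% of pre-truncation mass is negative "
            "for some features; realised CVs are biased downward",
            UserWarning,
        )
    sds = means * cvs
    a = (0.0 - means) / sds  # lower bound in standard units; upper = +inf
    out = truncnorm.rvs(
        a[:, None],
        np.inf,
        loc=means[:, None],
        scale=sds[:, None],
        size=(means.size, n_samples),
        random_state=rng,
    )
    return out


def _impose_exact_moments(
    block: np.ndarray, means: np.ndarray, cvs: np.ndarray
) -> np.ndarray:
    """Affinely rescale each feature's samples to exact sample mean and CV.

    After this transform the sample CV (n-1 SD over sample mean) of every
    feature equals its target exactly, so the measured change rate between
    groups equals 100 * (kappa - 1) by construction. At large CV the affine
    map can push individual values below zero (background-subtracted-intensity
    behaviour); group means stay positive.
    """
    xbar = block.mean(axis=1, keepdims=True)
    s = block.std(axis=1, ddof=1, keepdims=True)
    if np.any(s == 0):
        raise ValueError("cannot impose an exact CV on a zero-variance feature")
    target_sd = (cvs * means)[:, None]
    return means[:, None] + (block - xbar) * (target_sd / s)


def generate_matrix(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, SampleGroups, pd.DataFrame]:
    """Generate a case/control matrix plus ground-truth per-feature CVs.

    Returns (matrix, groups, truth) where truth has one row per feature with
    the drawn baseline mean, baseline CV and the two group-level target CVs.
    Reference-group samples come first in the column order.
    """
    rng = np.random.default_rng(spec.seed)
    means = np.exp(rng.normal(spec.mu_log_mean, spec.mu_log_sd, size=spec.n_features))
    cv_ref = _draw_truncated_gamma_cvs(
        rng, spec.n_features, spec.cv_mean, spec.cv_sd, spec.cv_max
    )
    cv_alt = cv_ref * spec.inflation_kappa
    draw = (
        _lognormal_draws
        if spec.noise_family == "lognormal"
        else _truncated_gaussian_draws
    )
    ref_block = draw(rng, means, cv_ref, spec.n_ref)
    alt_block = draw(rng, means * spec.mean_shift, cv_alt, spec.n_alt)
    if spec.exact_cv:
        ref_block = _impose_exact_moments(ref_block, means, cv_ref)
        alt_block = _impose_exact_moments(alt_block, means * spec.mean_shift, cv_alt)
    values = np.concatenate([ref_block, alt_block], axis=1)

    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = values.copy()
        values[mask] = np.nan

    feature_ids = pd.Index([f"feat{i:05d}" for i in range(spec.n_features)])
    sample_ids = [f"{spec.ref_label}{i + 1:02d}" for i in range(spec.n_ref)] + [
        f"{spec.alt_label}{i + 1:02d}" for i in range(spec.n_alt)
    ]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids), "linear"
    )
    groups = SampleGroups(
        assignment={
            s: (spec.ref_label if i < spec.n_ref else spec.alt_label)
            for i, s in enumerate(sample_ids)
        }
    )
    truth = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "mean": means,
            "cv_ref": cv_ref,
            "cv_alt": cv_alt,
        }
    )
    return matrix, groups, truth


def generate_qpcr(spec: QpcrSpec) -> tuple[CtTable, pd.DataFrame, pd.DataFrame]:
    """Generate a paired qPCR panel as a Ct table plus ground truth.

    Returns (ct_table, truth, gene_params). ``truth`` is long-format with the
    generated relative expression ``expression`` and its baseline-calibrated
    counterpart ``rq_calibrated`` (what comparative-Ct quantification of the
    emitted Ct table recovers, to floating-point accuracy). ``gene_params``
    records each gene's target mean and the two timepoint CVs.

    Generation is log-normal per gene: baseline log-values are
    mu_b + sigma_b * z_s; follow-up log-values share the subject component
    z_s with weight rho, use sigma_f = sqrt(ln(1 + (deflation * cv)^2)) and a
    mean-preserving location, so per-gene means are unchanged while CV
    shrinks by the deflation factor.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.panel)
    n_g, n_s = len(genes), spec.n_subjects
    mean = np.array([spec.panel[g][0] for g in genes])
    cv_b = np.array([spec.panel[g][1] / spec.panel[g][0] for g in genes])
    cv_f = cv_b * spec.deflation

    sig_b = np.sqrt(np.log1p(cv_b**2))
    sig_f = np.sqrt(np.log1p(cv_f**2))
    mu_b = np.log(mean) - sig_b**2 / 2.0
    mu_f = np.log(mean) - sig_f**2 / 2.0

    z = rng.standard_normal((n_g, n_s))
    eps = rng.standard_normal((n_g, n_s))
    x_b = np.exp(mu_b[:, None] + sig_b[:, None] * z)
    x_f = np.exp(
        mu_f[:, None]
        + sig_f[:, None] * (spec.rho * z + math.sqrt(1.0 - spec.rho**2) * eps)
    )

    subjects = [f"S{i + 1:02d}" for i in range(n_s)]
    timepoints = {spec.baseline_label: x_b, spec.followup_label: x_f}

    # Ct emission: dCt = -log2(expression); the reference gene's Ct is the
    # per-(subject, timepoint) stratum level, so Ct(gene) = ref_ct + dCt.
    ct_rows = []
    truth_rows = []
    for t_label, block in timepoints.items():
        ref_ct = rng.normal(spec.ref_ct_mean, spec.ref_ct_sd, size=n_s)
        dct = -np.log2(block)
        for si, subject in enumerate(subjects):
            ct_rows.append(
                {
                    "subject_id": subject,
                    "timepoint": t_label,
                    "gene": spec.ref_gene,
                    "ct": ref_ct[si],
                }
            )
            for gi, gene in enumerate(genes):
                ct_rows.append(
                    {
                        "subject_id": subject,
                        "timepoint": t_label,
                        "gene": gene,
                        "ct": ref_ct[si] + dct[gi, si],
                    }
                )
                truth_rows.append(
                    {
                        "subject_id": subject,
                        "timepoint": t_label,
                        "gene": gene,
                        "expression": block[gi, si],
                        "dct": dct[gi, si],
                    }
                )

    truth = pd.DataFrame(truth_rows)
    base_cal = (
        truth[truth["timepoint"] == spec.baseline_label]
        .groupby("gene")["dct"]
        .mean()
    )
    truth["rq_calibrated"] = np.exp2(-(truth["dct"] - base_cal.loc[truth["gene"]].to_numpy()))
    truth = truth.drop(columns="dct")

    gene_params = pd.DataFrame(
        {"gene": genes, "mean": mean, "cv_baseline": cv_b, "cv_followup": cv_f}
    )
    return CtTable(pd.DataFrame(ct_rows)), truth, gene_params


def matrix_preset(name: str, seed: int, **overrides) -> SyntheticSpec:
    """Named matrix specs emulating the two microarray dataset shapes.

    ``mrna``: 17199 features, 12 reference (control) vs 18 alternative (case)
    samples, baseline CVs ~ gamma(mean 0.062, SD 0.043), inflation 0.086/0.062.
    ``mirna``: 2967 features, 15 vs 15, CVs ~ gamma(0.81, 0.41), inflation
    0.97/0.81, with a 0.8x mean down-shift (the down-regulated small-RNA case).
    """
    presets = {
        "mrna": dict(
            n_features=17199,
            n_ref=12,
            n_alt=18,
            cv_mean=0.062,
            cv_sd=0.043,
            inflation_kappa=0.086 / 0.062,
        ),
        "mirna": dict(
            n_features=2967,
            n_ref=15,
            n_alt=15,
            cv_mean=0.81,
            cv_sd=0.41,
            inflation_kappa=0.97 / 0.81,
            mean_shift=0.8,
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    params = {**presets[name], "seed": seed, **overrides}
    return SyntheticSpec(**params)


def qpcr_preset(seed: int, **overrides) -> QpcrSpec:
    """The paired 17-gene x 30-subject panel spec with default deflation."""
    return QpcrSpec(seed=seed, **overrides)
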