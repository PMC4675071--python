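"""Result-table assembly, profile serialisation, and end-to-end pipeline runs.

Formatting conventions follow the compact style of published CV tables:
mean +/- SD pairs are printed to 3 decimals for small (microarray-intensity
scale, CV < 0.1) values and 2 decimals otherwise; change rates carry two
decimals and a percent sign; p-values are printed in scientific notation and
floored at 1e-30 (rendered "<1.00E-30") for display while the stored float
keeps full precision.

A pipeline run is reproducible from its persisted config: all result tables
carry the config hash, and a provenance record stores input digests, library
versions and the seed. Nothing in the output depends on wall-clock time, so
re-running a config byte-identically reproduces every table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from . import qpcr as eqpcr
from . import synthetic as esynth
from .variability import (
    CVProfile,
    VariabilityComparison,
    compare_cv,
    cv_density_summary,
    feature_cv,
)

__all__ = [
    "RunConfig",
    "format_mean_sd",
    "parse_mean_sd",
    "format_p",
    "build_comparison_table",
    "write_cv_profile",
    "read_cv_profile",
    "run_pipeline",
    "plot_cv_density",
]

P_DISPLAY_FLOOR = 1e-30

logger = logging.getLogger("exprvar")


def format_mean_sd(mean: float, sd: float) -> str:
    """Render ``mean +/- sd`` with scale-dependent precision."""
    digits = 2 if abs(mean) >= 0.1 else 3
    return f"{mean:.{digits}f} ± {sd:.{digits}f}"

_MEAN_SD_RE = re.compile(r"^\s*([-0-9.Ee+]+)\s*±\s*([-0-9.Ee+]+)\s*$")


def parse_mean_sd(text: str) -> tuple[float, float]:
    """Inverse of :func:`format_mean_sd` at displayed precision."""
    m = _MEAN_SD_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse mean ± sd from {text!r}")
    return float(m.group(1)), float(m.group(2))


def format_p(p: float) -> str:
    """Scientific-notation p-value with a display floor at 1e-30."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p outside [0, 1]")
    if p < P_DISPLAY_FLOOR:
        return "<1.00E-30"
    return f"{p:.2E}"


def build_comparison_table(
    comparisons: list[VariabilityComparison], labels: list[str] | None = None
) -> pd.DataFrame:
    """One formatted row per variability comparison (a Table-1-style layout)."""
    if not comparisons:
        raise ValueError("at least one comparison required")
    if labels is None:
        labels = [f"{c.ref_group} vs {c.alt_group}" for c in comparisons]
    rows = []
    for label, c in zip(labels, comparisons):
        assert np.isfinite(c.sd_cv_ref) and np.isfinite(c.sd_cv_alt), (
            "single-sample CV profiles cannot reach the report layer"
        )
        rows.append(
            {
                "comparison": label,
                "n_features": c.n_features,
                "ref": format_mean_sd(c.mean_cv_ref, c.sd_cv_ref),
                "alt": format_mean_sd(c.mean_cv_alt, c.sd_cv_alt),
                "change_rate": f"{c.change_rate_pct:.2f}%",
                "p": format_p(c.p_value),
                "test": c.test_name,
            }
        )
    return pd.DataFrame(rows)


def write_cv_profile(
    profile: CVProfile, path: str | Path, config_hash: str | None = None
) -> None:
    """Write a CV profile as TSV with its metadata in comment headers."""
    with open(path, "w") as fh:
        fh.write(f"# group={profile.group}\n")
        fh.write(f"# n_samples={profile.n_samples}\n")
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        profile.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_cv_profile(path: str | Path) -> CVProfile:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t")
    return CVProfile(
        group=meta.get("group", "unknown"),
        feature_ids=pd.Index(df["feature_id"].astype(str)),
        cv=df["cv"].to_numpy(),
        n_samples=int(meta.get("n_samples", 0)),
    )


@dataclass
class RunConfig:
    """Serializable description of a full pipeline run.

    ``microarray`` section: matrix, meta, scale, ref_group, alt_group, test.
    ``qpcr`` section: ct, ref_gene, baseline, followup, value.
    ``simulate`` section (optional, replaces input paths): preset and
    generator overrides; simulated inputs are written under outdir/data.
    """

    outdir: str
    seed: int = 0
    log_level: str = "INFO"
    microarray: dict | None = None
    qpcr: dict | None = None
    simulate: dict | None = None

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "log_level": self.log_level,
            "microarray": self.microarray,
            "qpcr": self.qpcr,
            "simulate": self.simulate,
        }

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured analyses; return the map of output names to paths.

    Stages: (optional) simulate inputs -> read -> validity filter -> per-group
    CV -> genome-wide comparison -> density export; and/or the qPCR chain
    read Ct -> comparative-Ct quantification -> per-gene paired tests + panel
    CV comparison. Any stage error aborts with the stage named in the log.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    outputs: dict[str, Path] = {}
    inputs: dict[str, str] = {}
    try:
        ma_cfg = dict(config.microarray) if config.microarray else None
        qpcr_cfg = dict(config.qpcr) if config.qpcr else None

        if config.simulate:
            sim = dict(config.simulate)
            preset = sim.pop("preset")
            datadir = outdir / "data"
            datadir.mkdir(exist_ok=True)
            logger.info("stage=simulate preset=%s seed=%d", preset, config.seed)
            if preset in {"mrna", "mirna"}:
                spec = esynth.matrix_preset(preset, seed=config.seed, **sim)
                matrix, groups, _truth = esynth.generate_matrix(spec)
                mpath = datadir / f"{preset}_matrix.tsv"
                eio.write_matrix(matrix, mpath)
                meta = pd.DataFrame(
                    {
                        "sample_id": list(groups.assignment),
                        "group": list(groups.assignment.values()),
                    }
                )
                metapath = datadir / f"{preset}_meta.tsv"
                meta.to_csv(metapath, sep="\t", index=False)
                ma_cfg = {
                    "matrix": str(mpath),
                    "meta": str(metapath),
                    "scale": "linear",
                    "ref_group": spec.ref_label,
                    "alt_group": spec.alt_label,
                    "test": (ma_cfg or {}).get("test", "signed-rank"),
                }
            elif preset == "qpcr":
                qspec = esynth.qpcr_preset(seed=config.seed, **sim)
                ct, _truth, _params = esynth.generate_qpcr(qspec)
                ct_path = datadir / "qpcr_ct.tsv"
                eio.write_ct_table(ct, ct_path)
                qpcr_cfg = {
                    "ct": str(ct_path),
                    "ref_gene": qspec.ref_gene,
                    "baseline": qspec.baseline_label,
                    "followup": qspec.followup_label,
                    **{k: v for k, v in (qpcr_cfg or {}).items() if k == "value"},
                }
            else:
                raise ValueError(f"unknown simulate preset {preset!r}")

        comparisons: list[VariabilityComparison] = []
        labels: list[str] = []

        if ma_cfg:
            logger.info("stage=read matrix=%s", ma_cfg["matrix"])
            matrix = eio.read_matrix(ma_cfg["matrix"], ma_cfg.get("scale", "linear"))
            groups = eio.read_sample_groups(ma_cfg["meta"])
            inputs[str(ma_cfg["matrix"])] = _sha256(Path(ma_cfg["matrix"]))
            inputs[str(ma_cfg["meta"])] = _sha256(Path(ma_cfg["meta"]))
            if matrix.scale == "log2":
                logger.info("stage=unlog")
                matrix = eio.unlog(matrix)
            logger.info("stage=filter")
            matrix, rep = eio.filter_valid_features(matrix, groups)
            logger.info(
                "filter dropped %d features (%d missing, %d non-positive)",
                rep.n_dropped, rep.n_missing_dropped, rep.n_nonpositive_dropped,
            )
            logger.info("stage=cv")
            ref = feature_cv(matrix, ma_cfg["ref_group"], groups)
            alt = feature_cv(matrix, ma_cfg["alt_group"], groups)
            for prof, tag in ((ref, "ref"), (alt, "alt")):
                p = outdir / f"cv_{tag}_{prof.group}.tsv"
                write_cv_profile(prof, p, chash)
                outputs[f"cv_{tag}"] = p
            logger.info("stage=compare")
            comparison = compare_cv(ref, alt, test=ma_cfg.get("test", "signed-rank"))
            comparisons.append(comparison)
            labels.append(f"{comparison.ref_group} vs {comparison.alt_group}")
            density = cv_density_summary([ref, alt])
            dpath = outdir / "cv_density.tsv"
            _write_table(density, dpath, chash)
            outputs["density"] = dpath

        if qpcr_cfg:
            qcfg = qpcr_cfg
            logger.info("stage=qpcr ct=%s", qcfg["ct"])
            ct = eio.read_ct_table(qcfg["ct"])
            inputs[str(qcfg["ct"])] = _sha256(Path(qcfg["ct"]))
            re_ = eqpcr.ddct_quantify(ct, qcfg["ref_gene"], qcfg["baseline"])
            genes = eqpcr.paired_gene_tests(
                re_, qcfg["baseline"], qcfg["followup"], value=qcfg.get("value", "rq")
            )
            gpath = outdir / "gene_changes.tsv"
            _write_table(genes, gpath, chash)
            outputs["genes"] = gpath
            panel = eqpcr.panel_cv_comparison(
                re_, qcfg["baseline"], qcfg["followup"], value=qcfg.get("value", "rq")
            )
            comparisons.append(panel)
            labels.append(f"panel {panel.ref_group} vs {panel.alt_group}")

        if comparisons:
            table = build_comparison_table(comparisons, labels)
            tpath = outdir / "comparison_table.tsv"
            _write_table(table, tpath, chash)
            outputs["comparison"] = tpath

        versions = {
            "exprvar": _package_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        provenance = {
            "config_hash": chash,
            "config": config.to_dict(),
            "inputs_sha256": inputs,
            "outputs": {k: str(v) for k, v in outputs.items()},
            "versions": versions,
            "seed": config.seed,
        }
        ppath = outdir / "provenance.json"
        ppath.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
        outputs["provenance"] = ppath
        config.to_yaml(outdir / "config.yaml")
        logger.info("run complete: %d output file(s)", len(outputs))
        return outputs
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("exprvar")
    except PackageNotFoundError:
        return "unknown"


def plot_cv_density(summary: pd.DataFrame, path: str | Path) -> None:
    """Plot per-group CV density curves with dashed mean markers."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for group, sub in summary.groupby("group", sort=False):
        (line,) = ax.plot(sub["x"], sub["density"], label=str(group))
        ax.axvline(sub["group_mean"].iloc[0], linestyle="--", color=line.get_color())
    ax.set_xlabel("coefficient of variation")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
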