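"""End-to-end pipeline: normalize -> KS threshold -> prevalence filter ->
PCA outlier removal -> hemolysis screen -> condition differential expression.

Every run is driven by a :class:`PipelineConfig` (loadable from YAML),
writes all intermediate tables under an output directory, and produces a
machine-readable report with per-stage accounting and provenance (config
hash + seed), such that identical config and seed reproduce identical
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from seromir import io_qc, normthresh, outlier
from seromir.nbglm import differential_expression
from seromir.synthdata import SynthConfig, SynthConfigError, simulate_counts

logger = logging.getLogger("seromir")


class ConfigError(ValueError):
    """One or more invalid pipeline-configuration fields."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "seromir_run"
    # input: either a synthetic-data config or paths to counts + metadata
    synth: SynthConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    counts_format: str = "tsv"
    # KS thresholding
    grid_max: float = 100.0
    grid_step: float = 1.0
    epsilon: float = 0.01
    max_pairs: int = 200
    ks_log_transform: bool = True
    # prevalence filter
    max_zero_fraction: float = 0.10
    # PCA outlier QC
    pca_n_features: int = 50
    pca_components: int = 3
    pca_n_sd: float = 3.0
    pca_flag_components: tuple[int, ...] = (1, 2, 3)
    # differential expression
    fdr: float = 0.05
    run_hemolysis_screen: bool = True
    run_condition_de: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synth is not None:
            d["synth"] = dataclasses.asdict(self.synth)
        d["pca_flag_components"] = list(self.pca_flag_components)
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        # output location is not part of the analysis identity
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config, reporting all field errors together."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["config file must contain a key-value mapping"])
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    for k in sorted(unknown):
        errors.append(f"unknown field {k!r}")
    kwargs = {k: v for k, v in raw.items() if k in known}

    synth_raw = kwargs.pop("synth", None)
    synth = None
    if synth_raw is not None:
        try:
            synth_fields = {f.name for f in dataclasses.fields(SynthConfig)}
            bad = set(synth_raw) - synth_fields
            if bad:
                errors.append(f"unknown synth field(s): {sorted(bad)}")
            synth_raw = {
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in synth_raw.items()
                if k in synth_fields
            }
            synth = SynthConfig(**synth_raw)
            synth.validate()
        except SynthConfigError as e:
            errors.append(f"synth: {e}")

    if "pca_flag_components" in kwargs:
        kwargs["pca_flag_components"] = tuple(kwargs["pca_flag_components"])
    cfg = PipelineConfig(synth=synth, **kwargs)

    if cfg.synth is None and (cfg.counts_path is None or cfg.metadata_path is None):
        errors.append(
            "either a 'synth' section or both 'counts_path' and "
            "'metadata_path' are required"
        )
    if cfg.counts_path and not Path(cfg.counts_path).exists():
        errors.append(f"counts_path does not exist: {cfg.counts_path}")
    if cfg.metadata_path and not Path(cfg.metadata_path).exists():
        errors.append(f"metadata_path does not exist: {cfg.metadata_path}")
    if cfg.grid_max <= 0 or cfg.grid_step <= 0:
        errors.append("grid_max and grid_step must be positive")
    if cfg.epsilon < 0:
        errors.append(f"epsilon must be >= 0, got {cfg.epsilon}")
    if not 0 <= cfg.max_zero_fraction <= 1:
        errors.append(f"max_zero_fraction must be in [0,1], got {cfg.max_zero_fraction}")
    if cfg.pca_n_sd <= 0:
        errors.append(f"pca_n_sd must be positive, got {cfg.pca_n_sd}")
    if cfg.pca_n_features < 1 or cfg.pca_components < 1:
        errors.append("pca_n_features and pca_components must be >= 1")
    if any(c < 1 or c > cfg.pca_components for c in cfg.pca_flag_components):
        errors.append(
            f"pca_flag_components must be within 1..{cfg.pca_components}"
        )
    if not 0 < cfg.fdr < 1:
        errors.append(f"fdr must be in (0,1), got {cfg.fdr}")
    if cfg.max_pairs < 1:
        errors.append(f"max_pairs must be >= 1, got {cfg.max_pairs}")
    if errors:
        raise ConfigError(errors)
    return cfg


@dataclass
class ReportBundle:
    stages: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    manifest: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "provenance": self.provenance,
            "manifest": sorted(self.manifest),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=float)


def _write(df: pd.DataFrame, path: Path, report: ReportBundle, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)
    report.manifest.append(path.name)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis; all artifacts land under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = ReportBundle()
    report.provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package": "seromir",
    }
    rng = np.random.default_rng(config.seed)

    # --- input ---------------------------------------------------------
    if config.synth is not None:
        synth_cfg = dataclasses.replace(config.synth, seed=config.seed)
        counts, meta, truth = simulate_counts(synth_cfg)
        io_qc.write_count_matrix(counts, out / "counts.tsv")
        report.manifest.append("counts.tsv")
        io_qc.write_sample_metadata(meta, out / "metadata.tsv")
        report.manifest.append("metadata.tsv")
        _write(truth.to_frame(), out / "ground_truth.tsv", report)
    else:
        counts = io_qc.read_count_matrix(config.counts_path, format=config.counts_format)
        meta = io_qc.read_sample_metadata(config.metadata_path)
        truth = None
    meta = meta.loc[counts.columns]
    report.stages["input"] = {
        "n_features": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
        "n_case": int((meta["condition"] == "case").sum()),
        "n_control": int((meta["condition"] == "control").sum()),
    }
    logger.info("input: %d features x %d samples", *counts.shape)

    # --- normalization -------------------------------------------------
    size_factors = normthresh.estimate_size_factors(counts)
    _write(size_factors.to_frame(), out / "size_factors.tsv", report)
    norm = normthresh.normalize(counts, size_factors)

    # --- KS threshold --------------------------------------------------
    grid = np.arange(0.0, config.grid_max + config.grid_step / 2, config.grid_step)
    pairs = normthresh.default_pairs(meta, max_pairs=config.max_pairs, rng=rng)
    scan = normthresh.threshold_scan(
        norm, pairs, grid=grid, log_transform=config.ks_log_transform
    )
    t_star = normthresh.select_threshold(scan, epsilon=config.epsilon)
    _write(scan.to_frame(), out / "threshold_scan.tsv", report, index=False)
    (out / "threshold.json").write_text(
        json.dumps(
            {"selected": t_star, "d_full": scan.d_full, "n_pairs": len(pairs)},
            sort_keys=True,
        )
    )
    report.manifest.append("threshold.json")
    retained = normthresh.mean_filter(norm, t_star)
    report.stages["ks_threshold"] = {
        "selected_threshold": float(t_star),
        "d_full": float(scan.d_full),
        "n_in": int(counts.shape[0]),
        "n_retained": int(len(retained)),
        "n_removed": int(counts.shape[0] - len(retained)),
    }
    logger.info("KS threshold t*=%.3g retains %d features", t_star, len(retained))
    counts = counts.loc[retained]

    # --- prevalence filter --------------------------------------------
    filtered = normthresh.prevalence_filter(counts, config.max_zero_fraction)
    report.stages["prevalence_filter"] = {
        "n_in": int(counts.shape[0]),
        "n_retained": int(filtered.shape[0]),
        "n_removed": int(counts.shape[0] - filtered.shape[0]),
    }
    counts = filtered
    (out / "retained_features.txt").write_text("\n".join(counts.index) + "\n")
    report.manifest.append("retained_features.txt")

    # --- PCA outlier QC ------------------------------------------------
    norm = normthresh.normalize(counts, size_factors)
    vst = outlier.variance_stabilize(norm)
    top = outlier.top_variable_features(vst, n=min(config.pca_n_features, vst.shape[0]))
    k = min(config.pca_components, vst.shape[1] - 1, len(top))
    pca = outlier.run_pca(vst.loc[top], k=k)
    flag_comps = tuple(c for c in config.pca_flag_components if c <= k)
    outliers = outlier.detect_outliers(pca, n_sd=config.pca_n_sd, components=flag_comps)
    _write(pca.sample_scores, out / "pca_scores.tsv", report)
    (out / "outliers.txt").write_text("\n".join(outliers) + ("\n" if outliers else ""))
    report.manifest.append("outliers.txt")
    report.stages["pca_outliers"] = {
        "n_samples_in": int(counts.shape[1]),
        "flagged": outliers,
        "n_samples_retained": int(counts.shape[1] - len(outliers)),
        "explained_variance": [float(v) for v in pca.explained_variance_fractions],
    }
    if outliers:
        logger.info("excluding PCA outlier sample(s): %s", ", ".join(outliers))
        keep = [s for s in counts.columns if s not in outliers]
        counts = counts[keep]
        meta = meta.loc[keep]
        # depth factors re-estimated on the retained cohort
        size_factors = normthresh.estimate_size_factors(counts)

    # --- differential expression --------------------------------------
    for term, enabled, fname in (
        ("absorbance", config.run_hemolysis_screen, "de_hemolysis.tsv"),
        ("condition", config.run_condition_de, "de_condition.tsv"),
    ):
        if not enabled:
            continue
        table = differential_expression(
            counts, meta, tested_term=term, size_factors=size_factors,
            alpha_fdr=config.fdr,
        )
        _write(table, out / fname, report)
        key = "hemolysis_screen" if term == "absorbance" else "condition_de"
        report.stages[key] = {
            "tested_term": term,
            "n_features": int(table.shape[0]),
            "n_significant": int(table["significant"].sum()),
        }
        logger.info(
            "%s: %d / %d significant at FDR %.2g",
            key, int(table["significant"].sum()), table.shape[0], config.fdr,
        )

    (out / "report.json").write_text(report.to_json())
    report.manifest.append("report.json")
    (out / "report.txt").write_text(_human_report(report))
    return report


def _human_report(report: ReportBundle) -> str:
    lines = [f"seromir run (config {report.provenance['config_hash']}, "
             f"seed {report.provenance['seed']})", ""]
    for stage, info in report.stages.items():
        lines.append(f"[{stage}]")
        for k, v in info.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    return "\n".join(lines)
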