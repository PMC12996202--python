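"""End-to-end orchestration: simulate -> QC -> features -> stats -> classify.

A run is configured by a YAML file with nested sections (``cohort``,
``qc``, ``kinematics``, ``stats``, ``cv``) plus a global seed, and writes
a reproducible output bundle: the feature table, QC report, the two
statistics tables (group comparisons and teacher-rating correlations),
domain corrections, the inter-regional correlation matrix, the
classification report with permutation importances and ROC coordinates,
a resolved-configuration log, and a manifest of content hashes.  The same
configuration and seed reproduce the bundle bit for bit.
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

from . import classify, kinematics, stats, synthetic
from .io import SessionRecording, read_metadata, read_session, write_metadata, write_session
from .qc import QcConfig

log = logging.getLogger("poseactivity")

REQUIRED_SECTIONS = ("cohort", "qc", "kinematics", "stats", "cv")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    cohort: synthetic.CohortSpec = field(default_factory=synthetic.CohortSpec)
    qc: QcConfig = field(default_factory=QcConfig)
    window: int = kinematics.DEFAULT_WINDOW
    alpha: float = 0.05
    cv: classify.CvConfig = field(default_factory=classify.CvConfig)
    families: tuple[str, ...] = classify.FAMILIES
    write_sessions: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        for section in REQUIRED_SECTIONS:
            if section not in raw:
                raise ConfigError(f"configuration missing required section {section!r}")
        seed = int(raw.get("seed", 0))
        try:
            cohort = synthetic.CohortSpec(**{**raw["cohort"], "seed": raw["cohort"].get("seed", seed)})
            qc = QcConfig(**raw["qc"])
            cv = classify.CvConfig(**{**raw["cv"], "seed": raw["cv"].get("seed", seed)})
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc
        kin = raw["kinematics"]
        st = raw["stats"]
        return cls(
            cohort=cohort, qc=qc, window=int(kin.get("window", kinematics.DEFAULT_WINDOW)),
            alpha=float(st.get("alpha", 0.05)), cv=cv,
            families=tuple(raw.get("families", classify.FAMILIES)),
            write_sessions=bool(raw.get("write_sessions", False)), seed=seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        return cls.from_dict(raw)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["cohort"]["age_range_months"] = list(self.cohort.age_range_months)
        return out


def default_config(seed: int = 0, **cohort_overrides) -> PipelineConfig:
    cohort = dataclasses.replace(synthetic.CohortSpec(seed=seed), **cohort_overrides)
    return PipelineConfig(cohort=cohort, cv=classify.CvConfig(seed=seed), seed=seed)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def stage_simulate(config: PipelineConfig, out_dir: Path) -> tuple[list[SessionRecording], pd.DataFrame]:
    sessions, metadata = synthetic.generate_cohort(config.cohort)
    write_metadata(metadata, out_dir / "metadata.csv")
    if config.write_sessions:
        sess_dir = out_dir / "sessions"
        sess_dir.mkdir(exist_ok=True)
        for s in sessions:
            write_session(s, sess_dir / f"{s.participant_id}.csv")
    log.info("simulate: %d sessions (%d risk / %d control)",
             len(sessions), config.cohort.n_risk, config.cohort.n_control)
    return sessions, metadata


def stage_features(
    config: PipelineConfig, sessions: list[SessionRecording], metadata: pd.DataFrame,
    out_dir: Path,
) -> pd.DataFrame:
    features, records = kinematics.build_feature_table(
        sessions, metadata, config.qc, config.window)
    qc_report = pd.DataFrame([dataclasses.asdict(r) for r in records])
    _write_csv(qc_report, out_dir / "qc_report.csv")
    _write_csv(features, out_dir / "features.csv")
    excluded = qc_report[qc_report["excluded"]]
    for _, row in excluded.iterrows():
        log.info("qc: excluded %s (missingness %.3f)", row["participant_id"], row["missingness"])
    log.info("features: %d participants retained, %d excluded", len(features), len(excluded))
    return features


def stage_stats(config: PipelineConfig, features: pd.DataFrame, out_dir: Path) -> dict:
    census = stats.normality_census(features, config.alpha)
    _write_csv(census, out_dir / "normality.csv")
    tests = stats.group_differences(features)
    _write_csv(tests, out_dir / "group_tests.csv")
    try:
        corr = stats.conners_correlations(features)
    except ValueError as exc:
        # degenerate (zero-variance) features: correlations undefined
        log.warning("stats: correlations undefined (%s); writing NaN table", exc)
        from .landmarks import STAT_REGIONS

        corr = pd.DataFrame(
            {"region": list(STAT_REGIONS), "rho": np.nan, "ci_low": np.nan,
             "ci_high": np.nan, "p": np.nan}
        )
    _write_csv(corr, out_dir / "correlations.csv")
    domains = stats.domain_bonferroni(
        {r: p for r, p in zip(tests["region"], tests["p_raw"])} |
        _hip_pvalues(features), config.alpha)
    dom_rows = []
    for d in domains:
        for region, sig in d.outcomes.items():
            dom_rows.append({"domain": d.domain, "m": d.m, "alpha_adj": d.alpha_adj,
                             "region": region, "significant": sig})
    _write_csv(pd.DataFrame(dom_rows), out_dir / "domain_corrections.csv")
    try:
        matrix = stats.spearman_matrix(features)
    except ValueError as exc:
        log.warning("stats: correlation matrix undefined (%s); writing NaN matrix", exc)
        from .landmarks import STAT_REGIONS

        matrix = pd.DataFrame(np.nan, index=list(STAT_REGIONS), columns=list(STAT_REGIONS))
    matrix.to_csv(out_dir / "correlation_matrix.csv")
    n_sig = int((tests["p_fdr"] < config.alpha).sum())
    log.info("stats: %d/%d regions significant after FDR", n_sig, len(tests))
    return {"tests": tests, "correlations": corr, "matrix": matrix, "census": census}


def _hip_pvalues(features: pd.DataFrame) -> dict[str, float]:
    """Hip-region raw p values for the domain sensitivity analysis.

    Hips are excluded from the main tables but belong to the lower-limb
    domains, so their Mann-Whitney p values are computed here.
    """
    out = {}
    risk = features[features["group"] == "risk"]
    control = features[features["group"] == "control"]
    for region in ("left_hip", "right_hip"):
        res = stats.mann_whitney(risk[region].to_numpy(), control[region].to_numpy())
        out[region] = res.p_raw
    return out


def stage_classify(config: PipelineConfig, features: pd.DataFrame, out_dir: Path) -> dict:
    x, y = classify.select_features(features)
    degenerate = x.columns[x.nunique() <= 1].tolist()
    if degenerate:
        log.warning("classify: degenerate (constant) features %s", degenerate)
    specs = classify.default_model_specs()
    rows, pfi_frames, roc_frames = [], [], []
    reports = {}
    for family in config.families:
        report = classify.nested_cv(x, y, specs[family], config.cv)
        reports[family] = report
        rows.append(classify.report_to_row(report))
        pfi = report.importances.rename(family)
        pfi_frames.append(pfi)
        roc_frames.append(classify.roc_points(report, y))
        log.info("classify: %s pooled AUC %.3f accuracy %.3f",
                 family, report.pooled_auc, report.metrics["accuracy"]["value"])
    demo = classify.demographic_baseline(
        features["age_months"].to_numpy(), features["sex"].to_numpy(), y, config.cv)
    reports["svm_demographic"] = demo
    rows.append(classify.report_to_row(demo))
    roc_frames.append(classify.roc_points(demo, y))

    ml_report = pd.DataFrame(rows)
    _write_csv(ml_report, out_dir / "ml_report.csv")
    with open(out_dir / "ml_report.json", "w", encoding="utf-8") as fh:
        json.dump(rows, fh, indent=2)
    pfi_table = pd.concat(pfi_frames, axis=1)
    pfi_table.index.name = "feature"
    pfi_table.reset_index().to_csv(out_dir / "pfi.csv", index=False)
    _write_csv(pd.concat(roc_frames, ignore_index=True), out_dir / "roc_points.csv")
    return reports


def write_manifest(out_dir: Path) -> dict[str, str]:
    """Content hashes of every data output (log and manifest excluded)."""
    manifest = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_dir() or path.name in ("manifest.json", "run.log"):
            continue
        manifest[str(path.relative_to(out_dir))] = hashlib.sha256(
            path.read_bytes()).hexdigest()
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the full output bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("resolved config: %s", json.dumps(config.resolved(), default=str, sort_keys=True))
        try:
            sessions, metadata = stage_simulate(config, out_dir)
        except Exception as exc:
            raise RuntimeError(f"simulate stage failed: {exc}") from exc
        try:
            features = stage_features(config, sessions, metadata, out_dir)
        except Exception as exc:
            raise RuntimeError(f"feature stage failed: {exc}") from exc
        try:
            stat_out = stage_stats(config, features, out_dir)
        except Exception as exc:
            raise RuntimeError(f"stats stage failed: {exc}") from exc
        try:
            reports = stage_classify(config, features, out_dir)
        except Exception as exc:
            raise RuntimeError(f"classify stage failed: {exc}") from exc
        manifest = write_manifest(out_dir)
        return {"features": features, "stats": stat_out, "reports": reports,
                "manifest": manifest}
    finally:
        log.removeHandler(handler)
        handler.close()


def rerun_from_features(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Recompute stats and classification from a cached features.csv."""
    out_dir = Path(out_dir)
    features = pd.read_csv(out_dir / "features.csv")
    stat_out = stage_stats(config, features, out_dir)
    reports = stage_classify(config, features, out_dir)
    manifest = write_manifest(out_dir)
    return {"features": features, "stats": stat_out, "reports": reports,
            "manifest": manifest}
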