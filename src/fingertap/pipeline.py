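"""End-to-end orchestration: synth -> preprocess -> features -> models.

A :class:`RunConfig` (YAML-loadable) names the cohort, feature profile,
contrasts and model settings; :func:`run_pipeline` executes the stages in
order, tolerates per-recording failures (logged and counted), and returns
a :class:`RunReport` whose numeric payload is reproducible bit-for-bit
under fixed seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import FingertapError, ParameterError, ValidationError
from .features import PROFILES, features_table
from .models import (
    add_common_scores,
    classify,
    diagnostics,
    feature_contributions,
    regress_severity,
    select_contrast,
)
from .preprocess import PreprocessConfig, preprocess_recording
from .recording import LANDMARKS, LandmarkRecording
from .synth import CohortDataset, CohortSpec, generate_cohort, small_cohort_spec

log = logging.getLogger("fingertap")

DEFAULT_CONTRASTS = (
    "ataxia_vs_control",
    "ataxia_vs_parkinsonism",
    "parkinsonism_vs_control",
)

REGRESSION_TARGETS = {
    "common_arm_dominant": "common_arm_dominant",
    "common_arm_nondominant": "common_arm_nondominant",
    "severity_dominant": "severity_dominant",
}


@dataclass
class RunConfig:
    """Settings for one reproducible pipeline run."""

    n_ataxia: int = 30
    n_parkinsonism: int = 30
    n_control: int = 30
    seed: int = 0
    profile: str = "canonical"
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS
    regression_targets: tuple[str, ...] = ("common_arm_dominant",)
    penalty: str = "l1"
    k: int = 10
    pca_scope: str = "per-fold"
    tune: str = "nested"
    n_bootstrap: int = 200
    out_dir: str | None = None
    strict: bool = False

    def validate(self) -> None:
        if self.profile not in PROFILES:
            raise ParameterError(
                f"unknown feature profile {self.profile!r}; available: {sorted(PROFILES)}"
            )
        for c in self.contrasts:
            select_contrast(pd.DataFrame({"group": [], "age": [], "common_arm_dominant": []}), c)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("contrasts", "regression_targets"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Consolidated output of one pipeline run."""

    config_hash: str
    version: str
    qc_summary: dict
    feature_manifest: dict
    model_reports: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config_hash": self.config_hash,
            "version": self.version,
            "qc_summary": self.qc_summary,
            "feature_manifest": self.feature_manifest,
            "failures": self.failures,
            "stage_seconds": self.stage_seconds,
            "models": {
                name: rep.metrics for name, rep in self.model_reports.items()
            },
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def preprocess_cohort(
    dataset: CohortDataset,
    config: PreprocessConfig | None = None,
    strict: bool = False,
) -> tuple[dict, dict, list]:
    """Preprocess every recording; returns (signals, qc summary, failures)."""
    signals = {}
    failures = []
    qc_totals = {"outliers": 0, "interpolated": 0, "unrecoverable_gaps": 0}
    for key, rec in dataset.recordings.items():
        try:
            sig = preprocess_recording(rec, config)
        except FingertapError as exc:
            if strict:
                raise
            failures.append((key, str(exc)))
            continue
        signals[key] = sig
        qc_totals["outliers"] += sig.qc.outlier_count
        qc_totals["interpolated"] += sig.qc.interpolated_count
        qc_totals["unrecoverable_gaps"] += sig.qc.unrecoverable_gap_count
    qc_totals["n_signals"] = len(signals)
    qc_totals["n_failures"] = len(failures)
    return signals, qc_totals, failures


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full synthetic-cohort analysis defined by ``config``."""
    config.validate()
    timings: dict[str, float] = {}
    failures: dict[str, list] = {}

    t0 = time.perf_counter()
    spec = small_cohort_spec(
        config.n_ataxia, config.n_parkinsonism, config.n_control, seed=config.seed
    )
    dataset = generate_cohort(spec)
    timings["synth"] = time.perf_counter() - t0
    log.info("synth: %d sessions", dataset.n_sessions)

    t0 = time.perf_counter()
    signals, qc_summary, pre_failures = preprocess_cohort(dataset, strict=config.strict)
    failures["preprocess"] = [f"{k}: {m}" for k, m in pre_failures]
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    table, manifest = features_table(signals, profile=config.profile)
    failures["features"] = [f"{sid}: {msg}" for sid, msg in manifest.pop("failures", [])]
    timings["features"] = time.perf_counter() - t0
    log.info("features: %d sessions x %d columns", *table.shape)

    manifest_df = add_common_scores(dataset.manifest).set_index("session_id")
    manifest_df = manifest_df.loc[table.index]

    report = RunReport(
        config_hash=config.config_hash(),
        version=__version__,
        qc_summary=qc_summary,
        feature_manifest=manifest,
        failures=failures,
    )

    t0 = time.perf_counter()
    for contrast in config.contrasts:
        try:
            mask = select_contrast(manifest_df.reset_index(), contrast).to_numpy()
            sub = table[mask]
            meta = manifest_df[mask]
            groups = sorted(meta["group"].unique())
            pos = "ataxia" if "ataxia" in groups else groups[0]
            mr = classify(
                sub, meta["group"], meta["subject_id"], contrast=contrast,
                penalty=config.penalty, k=min(config.k, meta["subject_id"].nunique() // 2),
                seed=config.seed, positive_label=pos, pca_scope=config.pca_scope,
                tune=config.tune, n_bootstrap=config.n_bootstrap,
            )
            mr.metrics["diagnostics"] = diagnostics(
                mr, meta["age"], meta["severity_dominant"]
            ).to_dict(orient="records")
            mr.metrics["top_contributions"] = (
                feature_contributions(mr.coefficients, mr.transform)
                .head(10)[["feature", "contribution"]]
                .to_dict(orient="records")
            )
            report.model_reports[contrast] = mr
        except FingertapError as exc:
            if config.strict:
                raise
            failures.setdefault("models", []).append(f"{contrast}: {exc}")

    for target in config.regression_targets:
        col = REGRESSION_TARGETS.get(target, target)
        try:
            mr = regress_severity(
                table, manifest_df[col], manifest_df["subject_id"], target=target,
                k=min(config.k, manifest_df["subject_id"].nunique() // 2),
                seed=config.seed, pca_scope=config.pca_scope, tune=config.tune,
                n_bootstrap=config.n_bootstrap,
            )
            report.model_reports[f"regress_{target}"] = mr
        except FingertapError as exc:
            if config.strict:
                raise
            failures.setdefault("models", []).append(f"regress {target}: {exc}")
    timings["models"] = time.perf_counter() - t0
    report.stage_seconds = {k: round(v, 3) for k, v in timings.items()}

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "features.csv")
        (out / "feature_manifest.json").write_text(json.dumps(manifest, indent=2))
        manifest_df.to_csv(out / "manifest.csv")
        for name, mr in report.model_reports.items():
            mr.to_json(out / f"model_{name}.json")
        report.to_json(out / "run_report.json")
    return report


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(path: str | Path) -> list[str]:
    """Schema checks on a directory of landmark CSVs + manifest.

    Verifies CSV columns, monotone frames, confidence ranges, and
    manifest/recording cross-references.  Returns a list of violation
    strings (empty = clean); never modifies data.
    """
    root = Path(path)
    if not root.exists():
        raise ValidationError(f"path does not exist: {root}")
    violations: list[str] = []
    manifest_path = root / "manifest.csv"
    manifest = None
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
        for col in ("session_id", "subject_id", "group"):
            if col not in manifest.columns:
                violations.append(f"manifest.csv: missing column {col!r}")
    rec_files = sorted(p for p in root.glob("*.csv") if p.name != "manifest.csv")
    seen_sessions = set()
    for f in rec_files:
        df = pd.read_csv(f)
        missing_cols = {"frame", "landmark", "x", "y"} - set(df.columns)
        if missing_cols:
            violations.append(f"{f.name}: missing columns {sorted(missing_cols)}")
            continue
        unknown = set(df["landmark"].unique()) - set(LANDMARKS)
        if unknown:
            violations.append(f"{f.name}: unknown landmarks {sorted(unknown)}")
        for lm, sub in df.groupby("landmark"):
            if np.any(np.diff(sub["frame"].to_numpy()) <= 0):
                violations.append(f"{f.name}: frames not strictly increasing for {lm}")
        if "confidence" in df.columns:
            conf = df["confidence"].dropna()
            if ((conf < 0) | (conf > 1)).any():
                violations.append(f"{f.name}: confidence outside [0, 1]")
        if "fs" in df.columns:
            rates = set(df["fs"].dropna().unique())
            if not rates.issubset({30, 60}):
                violations.append(f"{f.name}: field fs has unsupported rate {sorted(rates)}")
        stem = f.stem
        for hand in ("dominant", "nondominant"):
            if stem.endswith(f"_{hand}"):
                seen_sessions.add(stem[: -len(hand) - 1])
    if manifest is not None and "session_id" in manifest.columns:
        for sid in manifest["session_id"]:
            if sid not in seen_sessions:
                violations.append(f"manifest.csv: session {sid!r} has no recording files")
    return violations
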