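"""End-to-end pipeline orchestration.

``run_pipeline`` drives simulate/load -> preprocess -> characteristic points
-> features -> regression fit -> cross-validation (and optionally the
feature-count sweep), writing every artifact into a single run directory
with a manifest carrying the effective configuration, its hash, and the
seed, so runs are auditable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .errors import ConfigError
from .features import assemble_features
from .pca import PCAModel  # noqa: F401  (re-exported for model loading)
from .preprocess import preprocess_cohort
from .regression import (
    LABELS,
    CVConfig,
    cross_validate,
    feature_sweep,
    fit_ols,
    format_percent,
)
from .signals import PhaseConvention
from .simulate import CohortSpec, generate_cohort, paper_like_effects

log = logging.getLogger("gaitdx")


@dataclass
class PipelineConfig:
    """Validated pipeline settings; serialized into every run's manifest."""

    out_dir: str = "gaitdx_run"
    manifest: str | None = None  # existing cohort; None -> simulate
    seed: int = 0
    stance_fraction: float = 0.40
    alpha: float = 0.05
    min_run_length: int = 1
    t_variant: str = "student"
    k_composite: int | None = 3
    info_fraction: float | None = None
    mode: str = "full"
    k_folds: int = 5
    stratified: bool = True
    leakage_mode: str = "refit_all"
    run_sweep: bool = False
    simulate_effects: str = "paper_like"  # or "none"
    effect_d: float = 1.2
    interpolation: str = "linear"

    def __post_init__(self):
        if self.mode not in ("full", "composite_only"):
            raise ConfigError(f"mode must be full|composite_only, got {self.mode!r}")
        if self.simulate_effects not in ("paper_like", "none"):
            raise ConfigError("simulate_effects must be 'paper_like' or 'none'")
        if (self.k_composite is None) == (self.info_fraction is None):
            raise ConfigError("set exactly one of k_composite / info_fraction")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        PhaseConvention(self.stance_fraction)  # validates

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    run_dir: Path
    cv_accuracy: float
    n_characteristic_points: int
    feature_names: list[str] = field(default_factory=list)


def _load_or_simulate(config: PipelineConfig):
    if config.manifest:
        log.info("loading cohort from %s", config.manifest)
        return gio.read_cohort(config.manifest)
    spec = CohortSpec(seed=config.seed)
    if config.simulate_effects == "paper_like":
        spec.effects = paper_like_effects(spec, d=config.effect_d)
    log.info(
        "simulating cohort: %d ACLD legs, %d control legs, %d trials each",
        spec.n_acld,
        2 * spec.n_control_subjects,
        spec.trials_per_subject,
    )
    return generate_cohort(spec)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config": asdict(config), "config_hash": config.config_hash()}
    convention = PhaseConvention(config.stance_fraction)

    records = _load_or_simulate(config)
    cohort = preprocess_cohort(records, interpolation=config.interpolation)
    gio.write_processed_cohort(
        cohort,
        run_dir / "processed_cohort.csv",
        metadata={
            **meta,
            "grid_points": convention.n_points,
            "stance_fraction": config.stance_fraction,
            "processing_order": [
                "nondimensionalize",
                "resample",
                "average_trials",
                "amplitude_normalize",
            ],
        },
    )

    table, pipeline_model = assemble_features(
        cohort,
        convention=convention,
        k=config.k_composite,
        info_fraction=config.info_fraction,
        mode=config.mode,
        alpha=config.alpha,
        min_run_length=config.min_run_length,
        t_variant=config.t_variant,
    )
    gio.points_to_frame(pipeline_model.points).to_csv(
        run_dir / "characteristic_points.csv", index=False
    )
    table.to_csv(run_dir / "features.csv")
    (run_dir / "feature_pipeline.json").write_text(pipeline_model.to_json(indent=2))

    y = np.array([LABELS[g] for g in table["group"]])
    model = fit_ols(table, y)
    (run_dir / "diagnosis_model.json").write_text(model.to_json(indent=2))

    cv_cfg = CVConfig(
        k_folds=config.k_folds,
        seed=config.seed,
        stratified=config.stratified,
        leakage_mode=config.leakage_mode,
        mode=config.mode,
        k_composite=config.k_composite,
        info_fraction=config.info_fraction,
        alpha=config.alpha,
        min_run_length=config.min_run_length,
        t_variant=config.t_variant,
        convention=convention,
    )
    cv = cross_validate(cohort, cv_cfg)
    cv_report = {
        "leakage_mode": cv.leakage_mode,
        "seed": cv.seed,
        "pooled_confusion": {
            "TP": cv.pooled.TP,
            "FP": cv.pooled.FP,
            "FN": cv.pooled.FN,
            "TN": cv.pooled.TN,
        },
        "pooled_accuracy": cv.accuracy,
        "fold_accuracies": cv.fold_accuracies,
    }
    (run_dir / "cv_report.json").write_text(json.dumps(cv_report, indent=2))

    if config.run_sweep:
        sweep = feature_sweep(cohort, config=cv_cfg)
        sweep["accuracy"] = sweep["accuracy"].map(lambda a: format_percent(a))
        sweep.to_csv(run_dir / "feature_sweep.csv", index=False)

    coef_table = pd.DataFrame(
        {
            "feature": ["constant"] + model.feature_names,
            "coefficient": model.coefficients,
            "std_error": model.std_errors,
            "p_value": model.p_values,
        }
    )
    summary = [
        "# gaitdx run summary",
        f"- config hash: {meta['config_hash']}",
        f"- seed: {config.seed}",
        f"- subjects: {len(cohort)}",
        f"- characteristic points: {len(pipeline_model.points)}",
        f"- features: {config.mode}, k_composite={pipeline_model.k_composite}",
        f"- CV ({cv.leakage_mode}, {config.k_folds}-fold) pooled accuracy: "
        f"{format_percent(cv.accuracy)}",
        f"- full-fit R^2: {model.r_squared:.3f}, RMSE: {model.rmse:.2f}, "
        f"F-test p: {model.f_pvalue:.3g}",
        "",
        "```",
        coef_table.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        "```",
        "",
    ]
    (run_dir / "summary.md").write_text("\n".join(summary))
    (run_dir / "run_manifest.json").write_text(json.dumps(meta, indent=2))
    return PipelineResult(
        run_dir=run_dir,
        cv_accuracy=cv.accuracy,
        n_characteristic_points=len(pipeline_model.points),
        feature_names=model.feature_names,
    )
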