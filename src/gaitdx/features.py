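"""Regression feature assembly.

The classifier's feature table has two blocks:

* three *phase-summary* features — the first PCA score of (a) the 13 per-muscle
  stance-phase mean forces, (b) the 13 swing-phase mean forces, and (c) the
  swing-phase knee-flexion trajectory. Each block gets its own PCA and only
  the leading score is kept (its information content dominates). Stance-phase
  knee flexion is deliberately not a feature: its regression coefficient is
  not significant and it does not move the accuracy.
* k *composite-index* features — the leading PCA scores of the characteristic
  matrix (subject values at the significant-difference points).

All features are centered PCA scores, so every training column has mean zero.
The fitted :class:`FeaturePipelineModel` stores everything needed to project
a new subject without refitting (leak-free cross-validation, deployment).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .charpoints import (
    CharacteristicMatrix,
    CharacteristicPoint,
    build_characteristic_matrix,
    cohort_pointwise_ttests,
    select_characteristic_points,
)
from .errors import GaitdxError, GaitdxWarning, SchemaError
from .pca import PCAModel, pca_fit, pca_transform, retained_k
from .preprocess import ProcessedWaveforms, split_phases
from .signals import KNEE_FLEXION, MUSCLES, PhaseConvention

PHASE_FEATURE_NAMES = ("mean_stance_force", "mean_swing_force", "knee_flexion_swing")


def _phase_blocks(
    cohort: list[ProcessedWaveforms], convention: PhaseConvention
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw per-subject blocks: stance muscle means (n x 13), swing muscle
    means (n x 13), swing flexion values (n x 60 under the default split)."""
    stance_means, swing_means, swing_flex = [], [], []
    for pw in cohort:
        st = [split_phases(pw.signal(m), convention)[0].mean() for m in MUSCLES]
        sw = [split_phases(pw.signal(m), convention)[1].mean() for m in MUSCLES]
        stance_means.append(st)
        swing_means.append(sw)
        swing_flex.append(split_phases(pw.signal(KNEE_FLEXION), convention)[1])
    return (
        np.asarray(stance_means),
        np.asarray(swing_means),
        np.asarray(swing_flex),
    )


def phase_mean_features(
    cohort: list[ProcessedWaveforms], convention: PhaseConvention
) -> tuple[np.ndarray, dict[str, PCAModel]]:
    """The three phase-summary feature columns and their fitted PCAs.

    Returns an (n_subjects, 3) array ordered as
    (mean_stance_force, mean_swing_force, knee_flexion_swing).
    """
    if len(cohort) < 2:
        raise GaitdxError(f"need at least 2 subjects, got {len(cohort)}")
    blocks = _phase_blocks(cohort, convention)
    models: dict[str, PCAModel] = {}
    cols = []
    for name, block in zip(PHASE_FEATURE_NAMES, blocks):
        model = pca_fit(block)
        models[name] = model
        cols.append(pca_transform(model, block, k=1)[:, 0])
    return np.column_stack(cols), models


def composite_index_features(
    charmatrix: CharacteristicMatrix,
    k: int | None = None,
    info_fraction: float | None = None,
) -> tuple[np.ndarray, PCAModel | None, int]:
    """First k PCA score columns of the characteristic matrix.

    Either ``k`` or ``info_fraction`` selects the count; k is clipped (with a
    warning) to the number of characteristic points. Returns
    (scores n x k, fitted PCAModel or None when the matrix is empty, k).
    """
    n, n_cols = charmatrix.values.shape
    if (k is None) == (info_fraction is None):
        raise SchemaError("specify exactly one of k or info_fraction")
    if n_cols == 0 or (k is not None and k == 0):
        if k not in (0, None):
            warnings.warn(
                "no characteristic points: composite index is empty",
                GaitdxWarning,
                stacklevel=2,
            )
        return np.empty((n, 0)), None, 0
    model = pca_fit(charmatrix.values, column_labels=charmatrix.column_labels)
    if info_fraction is not None:
        k = retained_k(model, info_fraction)
    if k > n_cols:
        warnings.warn(
            f"k={k} exceeds the {n_cols} characteristic points; clipping",
            GaitdxWarning,
            stacklevel=2,
        )
        k = n_cols
    return pca_transform(model, charmatrix.values, k=k), model, k


@dataclass
class FeaturePipelineModel:
    """Everything needed to compute a subject's feature row with no refitting:
    the characteristic points, the four fitted PCAs, k, mode, and the phase
    convention."""

    convention: PhaseConvention
    mode: str  # "full" or "composite_only"
    k_composite: int
    points: list[CharacteristicPoint]
    phase_models: dict[str, PCAModel]  # empty in composite_only mode
    composite_model: PCAModel | None

    @property
    def feature_names(self) -> list[str]:
        names = list(PHASE_FEATURE_NAMES) if self.mode == "full" else []
        names += [f"CI_{i + 1}" for i in range(self.k_composite)]
        return names

    def to_dict(self) -> dict:
        return {
            "convention": {
                "stance_fraction": self.convention.stance_fraction,
                "n_points": self.convention.n_points,
            },
            "mode": self.mode,
            "k_composite": self.k_composite,
            "points": [
                {"signal": p.signal, "percent": p.percent, "p_value": p.p_value}
                for p in self.points
            ],
            "phase_models": {k: m.to_dict() for k, m in self.phase_models.items()},
            "composite_model": (
                self.composite_model.to_dict() if self.composite_model else None
            ),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "FeaturePipelineModel":
        return cls(
            convention=PhaseConvention(**d["convention"]),
            mode=d["mode"],
            k_composite=d["k_composite"],
            points=[CharacteristicPoint(**p) for p in d["points"]],
            phase_models={
                k: PCAModel.from_dict(m) for k, m in d["phase_models"].items()
            },
            composite_model=(
                PCAModel.from_dict(d["composite_model"])
                if d["composite_model"]
                else None
            ),
        )

    @classmethod
    def from_json(cls, s: str) -> "FeaturePipelineModel":
        return cls.from_dict(json.loads(s))


def assemble_features(
    cohort: list[ProcessedWaveforms],
    convention: PhaseConvention | None = None,
    k: int | None = 3,
    info_fraction: float | None = None,
    mode: str = "full",
    alpha: float = 0.05,
    min_run_length: int = 1,
    t_variant: str = "student",
) -> tuple[pd.DataFrame, FeaturePipelineModel]:
    """Fit the whole feature pipeline on a training cohort.

    Returns the feature table (a DataFrame indexed by subject id, with a
    ``group`` column last) and the fitted pipeline model.
    """
    if mode not in ("full", "composite_only"):
        raise SchemaError(f"mode must be 'full' or 'composite_only', got {mode!r}")
    convention = convention or PhaseConvention()
    groups = {pw.group for pw in cohort}
    if len(groups) < 2:
        raise GaitdxError(
            "cohort must contain both groups (pointwise t-tests are undefined "
            f"for a single group: {groups})"
        )
    pvals = cohort_pointwise_ttests(cohort, variant=t_variant)
    points = select_characteristic_points(pvals, alpha, min_run_length)
    charmatrix = build_characteristic_matrix(cohort, points)
    ci_scores, ci_model, k_eff = composite_index_features(
        charmatrix, k=k, info_fraction=info_fraction
    )

    blocks = []
    phase_models: dict[str, PCAModel] = {}
    if mode == "full":
        phase_cols, phase_models = phase_mean_features(cohort, convention)
        blocks.append(phase_cols)
    blocks.append(ci_scores)
    matrix = np.hstack(blocks) if blocks else np.empty((len(cohort), 0))

    model = FeaturePipelineModel(
        convention=convention,
        mode=mode,
        k_composite=k_eff,
        points=points,
        phase_models=phase_models,
        composite_model=ci_model,
    )
    table = pd.DataFrame(
        matrix,
        index=pd.Index([pw.subject_id for pw in cohort], name="subject_id"),
        columns=model.feature_names,
    )
    table["group"] = [pw.group for pw in cohort]
    return table, model


def project_subject(
    model: FeaturePipelineModel, subject: ProcessedWaveforms
) -> np.ndarray:
    """Feature row for one subject using only the stored means/loadings/points
    (no refitting). Matches the training table exactly for training subjects."""
    parts = []
    if model.mode == "full":
        blocks = _phase_blocks([subject], model.convention)
        for name, block in zip(PHASE_FEATURE_NAMES, blocks):
            parts.append(pca_transform(model.phase_models[name], block, k=1)[0])
    if model.k_composite > 0:
        row = np.array(
            [subject.signal(p.signal)[p.percent] for p in model.points]
        )
        parts.append(pca_transform(model.composite_model, row, k=model.k_composite))
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def project_cohort(
    model: FeaturePipelineModel, cohort: list[ProcessedWaveforms]
) -> pd.DataFrame:
    rows = [project_subject(model, pw) for pw in cohort]
    table = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(model.feature_names))),
        index=pd.Index([pw.subject_id for pw in cohort], name="subject_id"),
        columns=model.feature_names,
    )
    table["group"] = [pw.group for pw in cohort]
    return table
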