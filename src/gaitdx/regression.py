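"""Sign-coded linear-regression diagnosis.

Training labels are +1 (ACLD) and -1 (control); an ordinary least squares
fit of ``y = b0 + b1 x1 + ... + bq xq`` on the feature table gives a scalar
diagnostic score whose sign is the predicted class (ties, score exactly 0,
go to control — the conservative call for a surgical diagnosis).

Inference follows the classical OLS machinery: coefficient standard errors
from sigma^2 (X'X)^-1, two-sided t-tests with n - q - 1 degrees of freedom,
an overall F-test, R^2, and the residual standard error (reported as RMSE
with the n - q - 1 denominator).

Cross-validation offers two leakage policies:

* ``refit_all`` (default, statistically sound): characteristic points, all
  PCAs and the regression are re-derived inside every training fold; held-out
  subjects are projected through the frozen fold pipeline.
* ``reuse_features``: the feature table is computed once on the full cohort
  and only the regression is refit per fold. This mirrors the common (and
  optimistic) practice of selecting features before splitting; reports label
  which mode produced them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import GaitdxError, GaitdxWarning, SchemaError, SingularDesignError
from .features import assemble_features, project_subject
from .preprocess import ProcessedWaveforms
from .signals import GROUP_ACLD, GROUP_CONTROL, PhaseConvention

LABELS = {GROUP_ACLD: 1.0, GROUP_CONTROL: -1.0}


@dataclass
class DiagnosisModel:
    """Fitted OLS diagnostic model with inference statistics.

    ``coefficients[0]`` is the intercept; the rest follow ``feature_names``.
    """

    feature_names: list[str]
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    f_pvalue: float
    r_squared: float
    rmse: float
    n_samples: int

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "coefficients": self.coefficients.tolist(),
            "std_errors": self.std_errors.tolist(),
            "p_values": self.p_values.tolist(),
            "f_pvalue": self.f_pvalue,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "n_samples": self.n_samples,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "DiagnosisModel":
        return cls(
            feature_names=list(d["feature_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            std_errors=np.asarray(d["std_errors"], dtype=float),
            p_values=np.asarray(d["p_values"], dtype=float),
            f_pvalue=float(d["f_pvalue"]),
            r_squared=float(d["r_squared"]),
            rmse=float(d["rmse"]),
            n_samples=int(d["n_samples"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "DiagnosisModel":
        return cls.from_dict(json.loads(s))

    @classmethod
    def from_coefficients(
        cls, feature_names: list[str], coefficients
    ) -> "DiagnosisModel":
        """Build a prediction-only model from known coefficients (intercept
        first), e.g. a published fitted model; inference fields are NaN."""
        coefficients = np.asarray(coefficients, dtype=float)
        q = len(feature_names)
        if coefficients.size != q + 1:
            raise SchemaError(
                f"expected {q + 1} coefficients (intercept + {q}), "
                f"got {coefficients.size}"
            )
        nan = np.full(q + 1, np.nan)
        return cls(
            feature_names=list(feature_names),
            coefficients=coefficients,
            std_errors=nan.copy(),
            p_values=nan.copy(),
            f_pvalue=float("nan"),
            r_squared=float("nan"),
            rmse=float("nan"),
            n_samples=0,
        )


def _design_matrix(features: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        X = features.drop(columns=["group"], errors="ignore")
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i + 1}" for i in range(X.shape[1])]
    return X, names


def fit_ols(features, labels) -> DiagnosisModel:
    """Ordinary least squares with classical inference.

    ``features`` is a DataFrame (a ``group`` column, if present, is dropped)
    or array; ``labels`` the +/-1 outcome vector. Raises
    :class:`SingularDesignError` naming the collinear columns when the
    intercept-augmented design is rank deficient.
    """
    X, names = _design_matrix(features)
    y = np.asarray(labels, dtype=float)
    n, q = X.shape
    if y.size != n:
        raise SchemaError(f"{n} feature rows but {y.size} labels")
    if n < q + 2:
        raise GaitdxError(f"need at least q + 2 = {q + 2} samples, got {n}")
    D = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(D)
    if rank < q + 1:
        # identify offending columns from the QR diagonal
        _, r = np.linalg.qr(D)
        diag = np.abs(np.diag(r))
        bad = [
            (["intercept"] + names)[i]
            for i in range(q + 1)
            if diag[i] < 1e-10 * max(diag.max(), 1.0)
        ]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {q + 1}); "
            f"collinear columns: {bad}",
            collinear_columns=bad,
        )
    beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    df_resid = n - q - 1
    sigma2 = sse / df_resid if df_resid > 0 else float("nan")
    cov = sigma2 * np.linalg.inv(D.T @ D)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    p_values = 2 * stats.t.sf(np.abs(tvals), df_resid)
    r_squared = 1.0 - sse / sst if sst > 0 else 0.0
    if q > 0 and sse > 0:
        f_stat = ((sst - sse) / q) / (sse / df_resid)
        f_pvalue = float(stats.f.sf(f_stat, q, df_resid))
    elif q > 0:
        f_pvalue = 0.0  # perfect fit
    else:
        f_pvalue = float("nan")  # intercept-only model: no overall test
    return DiagnosisModel(
        feature_names=names,
        coefficients=beta,
        std_errors=se,
        p_values=np.asarray(p_values, dtype=float),
        f_pvalue=f_pvalue,
        r_squared=max(0.0, r_squared),
        rmse=float(np.sqrt(sigma2)),
        n_samples=n,
    )


def predict_outcome(model: DiagnosisModel, feature_row) -> float:
    """The linear diagnostic score b0 + sum(bi * xi)."""
    x = np.asarray(feature_row, dtype=float).ravel()
    q = len(model.feature_names)
    if x.size != q:
        raise SchemaError(f"feature row has {x.size} values, model expects {q}")
    return float(model.coefficients[0] + model.coefficients[1:] @ x)


def feature_contributions(model: DiagnosisModel, feature_row) -> pd.Series:
    """Per-term contributions (intercept, then bi * xi); sums to the score."""
    x = np.asarray(feature_row, dtype=float).ravel()
    vals = np.concatenate([[model.coefficients[0]], model.coefficients[1:] * x])
    return pd.Series(vals, index=["constant"] + list(model.feature_names))


def classify(y: float) -> str:
    """Positive score -> ACLD, else control (0 is a control call)."""
    if not np.isfinite(y):
        raise GaitdxError(f"non-finite diagnostic score {y}")
    return GROUP_ACLD if y > 0 else GROUP_CONTROL


@dataclass
class ConfusionCounts:
    """2x2 confusion counts with ACLD as the positive class."""

    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise SchemaError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.FN + other.FN,
            self.TN + other.TN,
        )


def confusion_from_predictions(true_groups, predicted_groups) -> ConfusionCounts:
    c = ConfusionCounts()
    for truth, pred in zip(true_groups, predicted_groups, strict=True):
        if truth == GROUP_ACLD:
            if pred == GROUP_ACLD:
                c.TP += 1
            else:
                c.FN += 1
        else:
            if pred == GROUP_ACLD:
                c.FP += 1
            else:
                c.TN += 1
    return c


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, specificity and F1 from the counts.

    Metrics with a zero denominator come back NaN with a warning.
    """
    if c.total == 0:
        raise GaitdxError("all confusion counts are zero")

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(
                f"{name} undefined (zero denominator)", GaitdxWarning, stacklevel=3
            )
            return float("nan")
        return num / den

    accuracy = (c.TP + c.TN) / c.total
    precision = _ratio(c.TP, c.TP + c.FP, "precision")
    recall = _ratio(c.TP, c.TP + c.FN, "recall")
    specificity = _ratio(c.TN, c.TN + c.FP, "specificity")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
        warnings.warn("f1 undefined", GaitdxWarning, stacklevel=2)
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
    }


def format_percent(x: float, decimals: int = 1) -> str:
    """Percent string with round-half-away-from-zero (81.35 -> '81.4%')."""
    if np.isnan(x):
        return "nan"
    scaled = x * 100 * 10**decimals
    rounded = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    return f"{rounded / 10 ** decimals:.{decimals}f}%"


@dataclass
class CVConfig:
    """Cross-validation settings (folds, stratification, leakage policy, and
    the feature-pipeline knobs re-applied inside each training fold)."""

    k_folds: int = 5
    seed: int = 0
    stratified: bool = True
    leakage_mode: str = "refit_all"  # or "reuse_features"
    mode: str = "full"
    k_composite: int | None = 3
    info_fraction: float | None = None
    alpha: float = 0.05
    min_run_length: int = 1
    t_variant: str = "student"
    convention: PhaseConvention = field(default_factory=PhaseConvention)

    def __post_init__(self):
        if self.leakage_mode not in ("refit_all", "reuse_features"):
            raise SchemaError(f"unknown leakage_mode {self.leakage_mode!r}")


@dataclass
class CVResult:
    """K-fold CV outcome: fold assignment per subject, per-fold confusion,
    pooled confusion over all held-out predictions, and the pooled accuracy."""

    fold_assignments: np.ndarray
    per_fold: list[ConfusionCounts]
    pooled: ConfusionCounts
    seed: int
    leakage_mode: str

    @property
    def accuracy(self) -> float:
        return (self.pooled.TP + self.pooled.TN) / self.pooled.total

    @property
    def fold_accuracies(self) -> list[float]:
        return [(c.TP + c.TN) / c.total for c in self.per_fold]


def _assemble(cohort, config: CVConfig):
    return assemble_features(
        cohort,
        convention=config.convention,
        k=config.k_composite,
        info_fraction=config.info_fraction,
        mode=config.mode,
        alpha=config.alpha,
        min_run_length=config.min_run_length,
        t_variant=config.t_variant,
    )


def cross_validate(
    cohort: list[ProcessedWaveforms], config: CVConfig | None = None
) -> CVResult:
    """Stratified k-fold CV of the full diagnostic pipeline.

    Under ``refit_all`` the whole feature pipeline (pointwise t-tests,
    characteristic points, all four PCAs) and the regression are re-derived
    on each training fold; under ``reuse_features`` the features come from a
    single full-cohort fit and only the regression is refit per fold.
    """
    config = config or CVConfig()
    labels = np.array([pw.group for pw in cohort])
    n = len(cohort)
    if config.stratified:
        counts = pd.Series(labels).value_counts()
        if (counts < config.k_folds).any():
            raise GaitdxError(
                f"stratified {config.k_folds}-fold CV needs >= {config.k_folds} "
                f"samples per class; got {counts.to_dict()}"
            )
        splitter = StratifiedKFold(
            n_splits=config.k_folds, shuffle=True, random_state=config.seed
        )
        splits = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=config.k_folds, shuffle=True, random_state=config.seed)
        splits = splitter.split(np.zeros(n))

    if config.leakage_mode == "reuse_features":
        full_table, _ = _assemble(cohort, config)
        full_X = full_table.drop(columns="group").to_numpy()

    fold_assignments = np.full(n, -1, dtype=int)
    per_fold: list[ConfusionCounts] = []
    for fold, (train_idx, test_idx) in enumerate(splits):
        fold_assignments[test_idx] = fold
        train_groups = set(labels[train_idx])
        if len(train_groups) < 2:
            raise GaitdxError(f"fold {fold}: a class is absent from the training split")
        y_train = np.array([LABELS[g] for g in labels[train_idx]])
        if config.leakage_mode == "refit_all":
            train_cohort = [cohort[i] for i in train_idx]
            table, pipeline = _assemble(train_cohort, config)
            X_train = table.drop(columns="group").to_numpy()
            model = fit_ols(X_train, y_train)
            preds = [
                classify(predict_outcome(model, project_subject(pipeline, cohort[i])))
                for i in test_idx
            ]
        else:
            model = fit_ols(full_X[train_idx], y_train)
            preds = [classify(predict_outcome(model, full_X[i])) for i in test_idx]
        per_fold.append(confusion_from_predictions(labels[test_idx], preds))

    pooled = sum(per_fold, ConfusionCounts())
    assert pooled.total == n
    return CVResult(
        fold_assignments=fold_assignments,
        per_fold=per_fold,
        pooled=pooled,
        seed=config.seed,
        leakage_mode=config.leakage_mode,
    )


#: The published feature-count sweep: (mode, k_composite) pairs written
#: "3 + k" (three phase features plus k composite features) or "0 + k"
#: (composite index only).
DEFAULT_SWEEP: tuple[tuple[str, int], ...] = (
    ("full", 1),
    ("full", 2),
    ("full", 3),
    ("full", 4),
    ("full", 5),
    ("composite_only", 1),
    ("composite_only", 3),
    ("composite_only", 8),
)


def feature_sweep(
    cohort: list[ProcessedWaveforms],
    sweep: tuple[tuple[str, int], ...] = DEFAULT_SWEEP,
    config: CVConfig | None = None,
) -> pd.DataFrame:
    """CV accuracy and full-fit composite-coefficient p-values across feature
    counts, one row per (mode, k) condition."""
    base = config or CVConfig()
    rows = []
    for mode, k in sweep:
        cfg = CVConfig(
            k_folds=base.k_folds,
            seed=base.seed,
            stratified=base.stratified,
            leakage_mode=base.leakage_mode,
            mode=mode,
            k_composite=k,
            alpha=base.alpha,
            min_run_length=base.min_run_length,
            t_variant=base.t_variant,
            convention=base.convention,
        )
        cv = cross_validate(cohort, cfg)
        table, _ = _assemble(cohort, cfg)
        y = np.array([LABELS[g] for g in table["group"]])
        model = fit_ols(table, y)
        ci_p = [
            float(model.p_values[1 + i])
            for i, name in enumerate(model.feature_names)
            if name.startswith("CI_")
        ]
        n_phase = 3 if mode == "full" else 0
        rows.append(
            {
                "features": f"{n_phase} + {k}",
                "composite_only": mode == "composite_only",
                "accuracy": cv.accuracy,
                "composite_p_values": ci_p,
            }
        )
    return pd.DataFrame(rows)
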