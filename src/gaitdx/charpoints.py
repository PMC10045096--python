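"""Characteristic-point selection by pointwise two-sample t-tests.

For every signal, a two-sided two-sample t-test compares the two groups at
each of the 101 cycle percents. Within each maximal run of consecutive
significant points (p < alpha), the percent with the smallest p-value is the
signal's *characteristic point* — the instant where the groups differ most.
The processed waveform values at all characteristic points, stacked over
subjects, form the characteristic matrix that the composite index compresses.

No correction for multiple comparisons is applied across the 101 points: the
run-minimum rule is the only filter, so the point set should be read as a
descriptive screening device, not as a family-wise inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import GaitdxError, GaitdxWarning, SchemaError
from .preprocess import ProcessedWaveforms
from .signals import N_POINTS, SIGNAL_INDEX, validate_signal


@dataclass
class PointwisePValues:
    """Per-signal vector of two-sided t-test p-values along the cycle."""

    signal: str
    p: np.ndarray

    def __post_init__(self):
        validate_signal(self.signal)
        self.p = np.asarray(self.p, dtype=float)


@dataclass(frozen=True)
class CharacteristicPoint:
    """A (signal, cycle percent) pair where the group difference peaks."""

    signal: str
    percent: int
    p_value: float

    @property
    def column_label(self) -> str:
        return f"{self.signal}@{self.percent}"


@dataclass
class CharacteristicMatrix:
    """Subjects x characteristic-points value matrix."""

    values: np.ndarray
    points: list[CharacteristicPoint]
    subject_ids: list[str]

    @property
    def column_labels(self) -> list[str]:
        return [p.column_label for p in self.points]


def pointwise_ttests(
    group_a: np.ndarray,
    group_b: np.ndarray,
    signal: str = "knee_flexion",
    variant: str = "student",
) -> PointwisePValues:
    """Two-sided two-sample t-test at every cycle point.

    ``variant`` selects the pooled-variance Student test (default) or the
    Welch test. Degenerate points where both groups have zero variance give
    p = 1 when the means agree (t = 0 convention) and p -> 0 with a warning
    when they differ.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise GaitdxError(
            f"need >= 2 subjects per group, got {a.shape[0]} and {b.shape[0]}"
        )
    if a.shape[1] != b.shape[1]:
        raise SchemaError("group matrices have different numbers of cycle points")
    if variant not in ("student", "welch"):
        raise SchemaError(f"unknown t-test variant {variant!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            result = stats.ttest_ind(a, b, axis=0, equal_var=(variant == "student"))
    p = np.asarray(result.pvalue, dtype=float)
    # numerically-zero within-group variance (identical subjects may differ
    # by float rounding after scaling and renormalization)
    scale = np.maximum(np.abs(a).max(axis=0), np.abs(b).max(axis=0)) + 1.0
    zero_var = (a.std(axis=0) <= 1e-9 * scale) & (b.std(axis=0) <= 1e-9 * scale)
    if zero_var.any():
        equal_means = np.isclose(
            a.mean(axis=0), b.mean(axis=0), rtol=1e-9, atol=1e-9
        )
        p[zero_var & equal_means] = 1.0
        if (zero_var & ~equal_means).any():
            warnings.warn(
                f"{signal}: zero within-group variance with unequal means at "
                f"{int((zero_var & ~equal_means).sum())} points; p set to 0",
                GaitdxWarning,
                stacklevel=2,
            )
            p[zero_var & ~equal_means] = 0.0
    return PointwisePValues(signal=signal, p=p)


def find_significant_runs(
    p: np.ndarray, alpha: float = 0.05, min_run_length: int = 1
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive indices with p < alpha, as inclusive
    (start, stop) pairs; runs shorter than ``min_run_length`` are dropped."""
    p = np.asarray(p, dtype=float)
    sig = p < alpha
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, sig.size - 1))
    return [(s, e) for s, e in runs if e - s + 1 >= min_run_length]


def select_characteristic_points(
    p_by_signal: list[PointwisePValues],
    alpha: float = 0.05,
    min_run_length: int = 1,
) -> list[CharacteristicPoint]:
    """One point per significant run per signal: the run's p-value minimum
    (earliest index on ties). Points come out sorted by canonical signal
    order, then percent."""
    points: list[CharacteristicPoint] = []
    ordered = sorted(p_by_signal, key=lambda pv: SIGNAL_INDEX[pv.signal])
    for pv in ordered:
        for start, stop in find_significant_runs(pv.p, alpha, min_run_length):
            segment = pv.p[start : stop + 1]
            idx = start + int(np.argmin(segment))  # argmin takes earliest tie
            points.append(
                CharacteristicPoint(
                    signal=pv.signal, percent=idx, p_value=float(pv.p[idx])
                )
            )
    return points


def cohort_pointwise_ttests(
    cohort: list[ProcessedWaveforms],
    signals: list[str] | None = None,
    variant: str = "student",
) -> list[PointwisePValues]:
    """Run pointwise t-tests (ACLD vs control) for every signal of a cohort."""
    from .signals import SIGNALS

    signals = list(signals) if signals is not None else list(SIGNALS)
    acld = [pw for pw in cohort if pw.group == "ACLD"]
    ctrl = [pw for pw in cohort if pw.group == "CONTROL"]
    if not acld or not ctrl:
        raise GaitdxError("cohort must contain both ACLD and CONTROL subjects")
    out = []
    for name in signals:
        a = np.stack([pw.signal(name) for pw in acld])
        b = np.stack([pw.signal(name) for pw in ctrl])
        out.append(pointwise_ttests(a, b, signal=name, variant=variant))
    return out


def build_characteristic_matrix(
    cohort: list[ProcessedWaveforms], points: list[CharacteristicPoint]
) -> CharacteristicMatrix:
    """values[i, j] = subject i's processed value of points[j]'s signal at
    points[j]'s percent."""
    if not points:
        warnings.warn(
            "empty characteristic-point list: 0-column matrix",
            GaitdxWarning,
            stacklevel=2,
        )
    n = len(cohort)
    values = np.empty((n, len(points)))
    for j, pt in enumerate(points):
        if pt.percent < 0 or pt.percent >= N_POINTS:
            raise SchemaError(f"characteristic point percent {pt.percent} out of range")
        for i, pw in enumerate(cohort):
            values[i, j] = pw.signal(pt.signal)[pt.percent]
    return CharacteristicMatrix(
        values=values,
        points=list(points),
        subject_ids=[pw.subject_id for pw in cohort],
    )
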