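"""Per-subject gait-waveform preprocessing.

Raw per-trial waveforms (muscle forces in N, knee flexion in degrees,
arbitrary length over exactly one gait cycle) are turned into one processed
waveform set per subject-leg:

1. muscle forces are nondimensionalized by body weight (mass * 9.8);
2. every signal is linearly resampled onto the 101-point 0..100 % cycle grid;
3. the (typically five) trials are averaged pointwise;
4. each averaged signal is amplitude-normalized by its within-cycle maximum,
   so values lie in [0, 1] with peak exactly 1.

Averaging before amplitude normalization means the normalization removes one
overall scale per signal per subject; the pipeline is therefore invariant to
multiplying a subject's raw forces by any positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import (
    DegenerateSignalWarning,
    InvalidSubjectError,
    NegativeFlexionWarning,
    SchemaError,
    TooShortTrialError,
)
from .signals import (
    GRAVITY,
    GROUPS,
    KNEE_FLEXION,
    N_POINTS,
    SIGNAL_INDEX,
    SIGNALS,
    PhaseConvention,
    is_muscle,
)

#: Below this value a signal's within-cycle maximum is treated as zero and
#: amplitude normalization is skipped (degenerate all-zero signal).
DEGENERATE_TOL = 1e-12


@dataclass
class GaitTrial:
    """One recorded gait cycle: a per-signal sample array.

    ``samples`` maps signal name -> 1-D array. All signals in a trial must
    have equal length >= 2; muscle forces must be non-negative.
    """

    trial_id: str
    samples: dict[str, np.ndarray]

    def __post_init__(self):
        lengths = set()
        for name, values in self.samples.items():
            if name not in SIGNAL_INDEX:
                raise SchemaError(f"trial {self.trial_id}: unknown signal {name!r}")
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 1:
                raise SchemaError(f"trial {self.trial_id}: {name} is not 1-D")
            if not np.isfinite(arr).all():
                raise SchemaError(f"trial {self.trial_id}: {name} has missing values")
            if is_muscle(name) and (arr < 0).any():
                raise SchemaError(
                    f"trial {self.trial_id}: negative force in muscle {name}"
                )
            self.samples[name] = arr
            lengths.add(arr.size)
        if len(lengths) > 1:
            raise SchemaError(
                f"trial {self.trial_id}: signals have unequal lengths {sorted(lengths)}"
            )

    @property
    def n_samples(self) -> int:
        return next(iter(self.samples.values())).size


@dataclass
class SubjectRecord:
    """A labeled subject-leg: group, leg, body mass, and its gait trials."""

    subject_id: str
    group: str
    leg: str
    mass_kg: float
    trials: list[GaitTrial]

    def __post_init__(self):
        if self.group not in GROUPS:
            raise InvalidSubjectError(
                f"{self.subject_id}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if not self.mass_kg > 0:
            raise InvalidSubjectError(
                f"{self.subject_id}: mass_kg must be positive, got {self.mass_kg}"
            )
        if not self.trials:
            raise InvalidSubjectError(f"{self.subject_id}: no trials")


@dataclass
class ProcessedWaveforms:
    """A subject-leg's processed waveform stack.

    ``values`` is a (n_signals, 101) array in canonical signal order,
    dimensionless, amplitude-normalized to [0, 1].
    """

    subject_id: str
    group: str
    leg: str
    values: np.ndarray

    def signal(self, name: str) -> np.ndarray:
        try:
            return self.values[SIGNAL_INDEX[name]]
        except KeyError:
            raise SchemaError(f"unknown signal {name!r}") from None

    @property
    def label(self) -> int:
        """+1 for ACLD, -1 for control (the regression outcome coding)."""
        return 1 if self.group == "ACLD" else -1


def nondimensionalize_force(values, mass_kg: float) -> np.ndarray:
    """Divide a force vector (N) by the subject's body weight, mass * 9.8."""
    if not mass_kg > 0:
        raise InvalidSubjectError(f"mass_kg must be positive, got {mass_kg}")
    return np.asarray(values, dtype=float) / (mass_kg * GRAVITY)


def resample_cycle(samples, n_points: int = N_POINTS, *, kind: str = "linear") -> np.ndarray:
    """Resample one cycle onto ``n_points`` uniformly spaced points.

    The input is assumed uniformly sampled over exactly one cycle; both
    endpoints are preserved exactly. ``kind`` is "linear" (default) or
    "cubic" (natural cubic spline).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1 or samples.size < 2:
        raise TooShortTrialError(
            f"need at least 2 samples to resample, got shape {samples.shape}"
        )
    x_old = np.linspace(0.0, 1.0, samples.size)
    x_new = np.linspace(0.0, 1.0, n_points)
    if kind == "linear":
        return np.interp(x_new, x_old, samples)
    if kind == "cubic":
        return CubicSpline(x_old, samples, bc_type="natural")(x_new)
    raise SchemaError(f"unknown interpolation kind {kind!r}")


def average_trials(trials: list[np.ndarray]) -> np.ndarray:
    """Pointwise arithmetic mean of per-trial cycle vectors."""
    if not trials:
        raise InvalidSubjectError("cannot average an empty trial list")
    stack = np.asarray(trials, dtype=float)
    return stack.mean(axis=0)


def amplitude_normalize(curve, *, context: str = "") -> np.ndarray:
    """Scale a cycle waveform by its within-cycle maximum to peak at 1.

    If the maximum is numerically zero the curve is returned unchanged with
    a :class:`DegenerateSignalWarning` so cohorts with an inactive muscle
    still process.
    """
    curve = np.asarray(curve, dtype=float)
    peak = curve.max()
    if peak <= DEGENERATE_TOL:
        warnings.warn(
            f"degenerate (all-zero) signal{': ' + context if context else ''}; "
            "amplitude normalization skipped",
            DegenerateSignalWarning,
            stacklevel=2,
        )
        return curve.copy()
    return curve / peak


def preprocess_subject(
    record: SubjectRecord,
    n_points: int = N_POINTS,
    *,
    interpolation: str = "linear",
) -> ProcessedWaveforms:
    """Run the full preprocessing pipeline for one subject-leg.

    Order: nondimensionalize -> resample -> average trials -> amplitude
    normalize. Knee flexion skips nondimensionalization (it is an angle);
    negative flexion values (hyperextension) are carried through with a
    warning, since normalization by the signed maximum may leave them < 0.
    """
    missing = [s for s in SIGNALS for t in record.trials if s not in t.samples]
    if missing:
        raise SchemaError(
            f"{record.subject_id}: trials missing signals {sorted(set(missing))}"
        )
    out = np.empty((len(SIGNALS), n_points))
    for i, name in enumerate(SIGNALS):
        per_trial = []
        for trial in record.trials:
            raw = trial.samples[name]
            if is_muscle(name):
                raw = nondimensionalize_force(raw, record.mass_kg)
            try:
                per_trial.append(resample_cycle(raw, n_points, kind=interpolation))
            except TooShortTrialError as exc:
                raise TooShortTrialError(
                    f"{record.subject_id}/{trial.trial_id}/{name}: {exc}"
                ) from exc
        mean_curve = average_trials(per_trial)
        if name == KNEE_FLEXION and (mean_curve < 0).any():
            warnings.warn(
                f"{record.subject_id}: knee flexion has negative values "
                "(hyperextension); normalized values may fall below 0",
                NegativeFlexionWarning,
                stacklevel=2,
            )
        out[i] = amplitude_normalize(
            mean_curve, context=f"{record.subject_id}/{name}"
        )
    return ProcessedWaveforms(
        subject_id=record.subject_id, group=record.group, leg=record.leg, values=out
    )


def preprocess_cohort(
    records: list[SubjectRecord], n_points: int = N_POINTS, **kwargs
) -> list[ProcessedWaveforms]:
    return [preprocess_subject(r, n_points, **kwargs) for r in records]


def split_phases(curve, convention: PhaseConvention) -> tuple[np.ndarray, np.ndarray]:
    """Split a cycle vector into (stance values, swing values).

    Concatenating the two parts restores the input.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size != convention.n_points:
        raise SchemaError(
            f"curve length {curve.size} != grid size {convention.n_points}"
        )
    b = convention.boundary
    return curve[: b + 1], curve[b + 1 :]


def relabel(pw: ProcessedWaveforms, group: str) -> ProcessedWaveforms:
    """Copy of a processed record with a different group label (permutation tests)."""
    return replace(pw, group=group)
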