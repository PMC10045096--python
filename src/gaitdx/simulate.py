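"""Synthetic two-group jogging cohorts.

The generator emulates the statistical structure the analysis pipeline
assumes: a cohort of ACL-deficient legs (default 25) and control legs
(default 9 volunteers contributing both legs, 18 records), five trials per
leg, smooth cyclic waveforms for knee flexion and the 13 muscle forces, and
group mean differences localized in configurable gait-cycle windows.

Each leg's raw trial waveform for a signal is

    scale * clip( template(t) + subject_offset(t) + effect(t) + trial_noise(t), 0 )

where ``template`` is a fixed per-signal shape (periodic Gaussian bumps,
peak 1), ``subject_offset`` and ``trial_noise`` are smooth zero-mean periodic
random curves (few-term random Fourier series, so pointwise t-tests see
realistic autocorrelation rather than white noise), ``effect`` is the sum of
the cohort's :class:`EffectSpec` shifts (ACLD legs only, applied in raw units
*before* amplitude normalization, where real group differences arise), and
``scale`` converts template units to newtons (muscles, via body weight times
a per-muscle peak-force factor) or degrees (knee flexion). Body masses are
drawn per person from group-specific normals (ACLD 82.04 +/- 11.55 kg,
control 74.06 +/- 4.73 kg, the cohort the defaults emulate).

Because preprocessing amplitude-normalizes per signal, the absolute scales
cancel; they exist so the raw CSVs look like plausible gait data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ConfigError
from .preprocess import GaitTrial, SubjectRecord
from .signals import KNEE_FLEXION, SIGNALS, validate_signal

#: Template shapes: per signal, a list of periodic Gaussian bumps
#: (center %, width sigma %, relative amplitude). Peaks are renormalized to 1.
#: Shapes follow jogging electromyography convention: quadriceps and triceps
#: surae load in stance, hamstrings in late swing / terminal stance, a
#: biphasic knee-flexion curve with the swing wave dominant.
_TEMPLATE_BUMPS: dict[str, list[tuple[float, float, float]]] = {
    KNEE_FLEXION: [(15, 7, 0.45), (72, 10, 1.0)],
    "RF": [(18, 8, 1.0), (85, 7, 0.35)],
    "POP": [(12, 6, 0.8), (55, 12, 1.0)],
    "VAS": [(15, 7, 1.0), (95, 5, 0.25)],
    "GL": [(27, 8, 1.0)],
    "GM": [(25, 8, 1.0)],
    "SOLm": [(30, 9, 1.0)],
    "SOLl": [(31, 9, 1.0)],
    "ST": [(90, 7, 1.0), (38, 10, 0.45)],
    "SM": [(92, 7, 1.0), (40, 10, 0.5)],
    "SAp": [(68, 10, 1.0), (5, 6, 0.3)],
    "SAd": [(70, 10, 1.0), (8, 6, 0.3)],
    "BFlh": [(88, 8, 1.0), (35, 10, 0.5)],
    "BFsh": [(80, 9, 1.0), (30, 10, 0.35)],
}

#: Peak amplitude of each raw signal: degrees for knee flexion, multiples of
#: body weight for muscle forces (so raw force = factor * mass * 9.8 at peak).
_RAW_SCALE_BW = {
    KNEE_FLEXION: 80.0,  # degrees, peak swing flexion while jogging
    "RF": 1.2, "POP": 0.3, "VAS": 4.0, "GL": 1.5, "GM": 2.5,
    "SOLm": 3.0, "SOLl": 2.0, "ST": 0.8, "SM": 1.5, "SAp": 0.2,
    "SAd": 0.2, "BFlh": 1.0, "BFsh": 0.5,
}

#: Body-mass distributions (mean kg, sd kg) per group.
MASS_DISTRIBUTIONS = {"ACLD": (82.04, 11.55), "CONTROL": (74.06, 4.73)}


def _periodic_gaussian(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Gaussian bump on the cyclic 0..100 axis (wrapped copies keep the
    curve continuous across the cycle boundary)."""
    out = np.zeros_like(t, dtype=float)
    for shift in (-100.0, 0.0, 100.0):
        out += np.exp(-((t - center - shift) ** 2) / (2.0 * sigma**2))
    return out


@lru_cache(maxsize=None)
def _template_peak(signal: str) -> float:
    bumps = _TEMPLATE_BUMPS[signal]
    dense = np.linspace(0.0, 100.0, 1001)
    return max(
        sum(
            amp * _periodic_gaussian(dense, center, sigma)
            for center, sigma, amp in bumps
        ).max(),
        1e-12,
    )


@lru_cache(maxsize=None)
def _template_cached(signal: str, n_samples: int) -> np.ndarray:
    t = np.linspace(0.0, 100.0, n_samples)
    curve = np.zeros_like(t)
    for center, sigma, amp in _TEMPLATE_BUMPS[signal]:
        curve += amp * _periodic_gaussian(t, center, sigma)
    out = curve / _template_peak(signal)
    out.setflags(write=False)
    return out


def _template(signal: str, t: np.ndarray) -> np.ndarray:
    curve = np.zeros_like(t, dtype=float)
    for center, sigma, amp in _TEMPLATE_BUMPS[signal]:
        curve += amp * _periodic_gaussian(t, center, sigma)
    return curve / _template_peak(signal)


def default_base_waveforms() -> dict[str, np.ndarray]:
    """The shipped per-signal template curves on the 101-point grid
    (values in [0, 1], peak 1)."""
    t = np.arange(101.0)
    return {name: _template(name, t) for name in SIGNALS}


@dataclass(frozen=True)
class EffectSpec:
    """A localized group mean shift: ``amplitude`` (template units, i.e.
    fractions of the signal's peak) at the window center, tapering to ~0 at
    the window edges. ``shape`` is "gaussian_bump" or "plateau"."""

    signal: str
    window: tuple[float, float]
    amplitude: float
    shape: str = "gaussian_bump"

    def __post_init__(self):
        validate_signal(self.signal)
        start, end = self.window
        if not (0 <= start < end <= 100):
            raise ConfigError(
                f"effect window ({start}, {end}) must satisfy 0 <= start < end <= 100"
            )
        if self.shape not in ("gaussian_bump", "plateau"):
            raise ConfigError(f"unknown effect shape {self.shape!r}")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        start, end = self.window
        center = 0.5 * (start + end)
        width = end - start
        if self.shape == "gaussian_bump":
            sigma = width / 6.0  # edges sit at 3 sigma (~1% of the peak)
            return self.amplitude * _periodic_gaussian(t, center, sigma)
        ramp = 0.2 * width
        out = np.zeros_like(t, dtype=float)
        inside = (t >= start) & (t <= end)
        out[inside] = 1.0
        rise = inside & (t < start + ramp)
        fall = inside & (t > end - ramp)
        out[rise] = 0.5 * (1 - np.cos(math.pi * (t[rise] - start) / ramp))
        out[fall] = 0.5 * (1 - np.cos(math.pi * (end - t[fall]) / ramp))
        return self.amplitude * out


@dataclass
class CohortSpec:
    """Cohort-level generating conditions.

    ``subject_sd`` and ``trial_sd`` are pointwise standard deviations of the
    smooth subject-offset and trial-noise curves, in template units
    (fractions of the signal peak).
    """

    n_acld: int = 25
    n_control_subjects: int = 9  # each contributes both legs
    trials_per_subject: int = 5
    samples_per_trial: int = 100
    subject_sd: float = 0.08
    trial_sd: float = 0.05
    subject_harmonics: int = 3
    trial_harmonics: int = 8
    effects: list[EffectSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_acld < 2 or self.n_control_subjects < 1:
            raise ConfigError("need >= 2 ACLD legs and >= 1 control subject")
        if self.trials_per_subject < 1:
            raise ConfigError("trials_per_subject must be >= 1")
        if self.samples_per_trial < 2:
            raise ConfigError("samples_per_trial must be >= 2")
        if self.subject_sd < 0 or self.trial_sd < 0:
            raise ConfigError("standard deviations must be >= 0")

    @property
    def averaged_sd(self) -> float:
        """Pointwise sd of a trial-averaged subject curve: the between-subject
        spread a pointwise t-test sees (before amplitude normalization)."""
        return math.sqrt(
            self.subject_sd**2 + self.trial_sd**2 / self.trials_per_subject
        )

    def effect_amplitude_for_d(self, d: float) -> float:
        """Effect amplitude giving approximately Cohen's d at the window
        center on trial-averaged curves."""
        return d * self.averaged_sd


def _smooth_noise(rng: np.random.Generator, t: np.ndarray, sd: float, harmonics: int) -> np.ndarray:
    """Zero-mean periodic random curve with pointwise sd ``sd``: a random
    Fourier series over the 0..100 cycle."""
    if sd == 0.0 or harmonics == 0:
        return np.zeros_like(t, dtype=float)
    h = np.arange(1, harmonics + 1)
    a = rng.standard_normal(harmonics)
    b = rng.standard_normal(harmonics)
    phase = 2.0 * math.pi * np.outer(t, h) / 100.0
    series = np.cos(phase) @ a + np.sin(phase) @ b
    return sd / math.sqrt(harmonics) * series


def _generate_record(
    rng: np.random.Generator,
    spec: CohortSpec,
    subject_id: str,
    group: str,
    leg: str,
    mass_kg: float,
) -> SubjectRecord:
    n = spec.samples_per_trial
    t = np.linspace(0.0, 100.0, n)
    effect_by_signal: dict[str, np.ndarray] = {}
    if group == "ACLD":
        for eff in spec.effects:
            effect_by_signal.setdefault(eff.signal, np.zeros_like(t))
            effect_by_signal[eff.signal] += eff.evaluate(t)

    subject_curves = {}
    for name in SIGNALS:
        curve = _template_cached(name, n) + _smooth_noise(
            rng, t, spec.subject_sd, spec.subject_harmonics
        )
        if name in effect_by_signal:
            curve = curve + effect_by_signal[name]
        subject_curves[name] = curve

    trials = []
    for j in range(spec.trials_per_subject):
        samples = {}
        for name in SIGNALS:
            curve = subject_curves[name] + _smooth_noise(
                rng, t, spec.trial_sd, spec.trial_harmonics
            )
            if name == KNEE_FLEXION:
                samples[name] = _RAW_SCALE_BW[name] * np.clip(curve, 0.0, None)
            else:
                scale = _RAW_SCALE_BW[name] * mass_kg * 9.8
                samples[name] = scale * np.clip(curve, 0.0, None)
        trials.append(GaitTrial(trial_id=f"{subject_id}_{leg}_t{j + 1}", samples=samples))
    return SubjectRecord(
        subject_id=subject_id, group=group, leg=leg, mass_kg=mass_kg, trials=trials
    )


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the cohort: one record per ACLD leg (affected side only) and
    two records per control subject (both legs). Reproducible given
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    mean, sd = MASS_DISTRIBUTIONS["ACLD"]
    for i in range(spec.n_acld):
        mass = max(40.0, rng.normal(mean, sd))
        records.append(
            _generate_record(rng, spec, f"A{i + 1:02d}", "ACLD", "affected", mass)
        )
    mean, sd = MASS_DISTRIBUTIONS["CONTROL"]
    for i in range(spec.n_control_subjects):
        mass = max(40.0, rng.normal(mean, sd))
        for leg in ("left", "right"):
            records.append(
                _generate_record(rng, spec, f"C{i + 1:02d}", "CONTROL", leg, mass)
            )
    return records


def paper_like_effects(spec: CohortSpec, d: float = 1.2) -> list[EffectSpec]:
    """A preset of localized group differences of the kind reported for
    ACL-deficient jogging: reduced quadriceps loading and increased hamstring
    loading around terminal stance, and reduced swing-phase knee flexion.
    ``d`` is the approximate per-window Cohen's d on trial-averaged curves."""
    a = spec.effect_amplitude_for_d(d)
    return [
        EffectSpec("RF", (25, 45), -a),
        EffectSpec("VAS", (25, 45), -a),
        EffectSpec("ST", (30, 50), +a),
        EffectSpec("SM", (30, 50), +a),
        EffectSpec("BFlh", (30, 50), +a),
        EffectSpec(KNEE_FLEXION, (60, 80), -a),
    ]
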