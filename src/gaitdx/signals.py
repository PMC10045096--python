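"""Signal registry and gait-cycle conventions.

The pipeline analyses one joint angle (knee flexion, degrees) and the forces
of 13 knee-spanning muscles (newtons) over a single gait cycle, time-normalized
to 101 points (0..100 % inclusive, integer percent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

#: Standard gravitational acceleration used for force nondimensionalization
#: (force / (mass * G) gives force in units of body weight).
GRAVITY = 9.8

#: Number of points on the time-normalized cycle grid (0..100 % inclusive).
N_POINTS = 101

KNEE_FLEXION = "knee_flexion"

#: The 13 muscles, in canonical order: rectus femoris, popliteus, vastus,
#: gastrocnemius lateralis/medialis, soleus medialis/lateralis,
#: semitendinosus, semimembranosus, proximal/distal sartorius,
#: biceps femoris long/short head.
MUSCLES = (
    "RF", "POP", "VAS", "GL", "GM", "SOLm", "SOLl",
    "ST", "SM", "SAp", "SAd", "BFlh", "BFsh",
)

#: Full signal order: knee flexion first, then the 13 muscles.
SIGNALS = (KNEE_FLEXION,) + MUSCLES

SIGNAL_INDEX = {name: i for i, name in enumerate(SIGNALS)}

GROUP_ACLD = "ACLD"
GROUP_CONTROL = "CONTROL"
GROUPS = (GROUP_ACLD, GROUP_CONTROL)


def is_muscle(name: str) -> bool:
    return name in MUSCLES


def validate_signal(name: str) -> str:
    if name not in SIGNAL_INDEX:
        raise ConfigError(f"unknown signal {name!r}; admissible: {SIGNALS}")
    return name


@dataclass(frozen=True)
class PhaseConvention:
    """Fixed stance/swing split of the time-normalized cycle.

    ``stance_fraction`` is the fraction of the cycle with the foot on the
    ground; indices ``0..round(100 * stance_fraction)`` (inclusive) are
    stance, the remainder swing. The default 0.40 is typical of jogging.
    The boundary is a cohort-level configuration, not detected per subject.
    """

    stance_fraction: float = 0.40
    n_points: int = field(default=N_POINTS)

    def __post_init__(self):
        if not (0.0 < self.stance_fraction < 1.0):
            raise ConfigError(
                f"stance_fraction must be in (0, 1), got {self.stance_fraction}"
            )
        if self.n_points < 3:
            raise ConfigError("n_points must be at least 3")

    @property
    def boundary(self) -> int:
        """Last index belonging to stance."""
        return int(round((self.n_points - 1) * self.stance_fraction))

    @property
    def stance_indices(self) -> np.ndarray:
        return np.arange(0, self.boundary + 1)

    @property
    def swing_indices(self) -> np.ndarray:
        return np.arange(self.boundary + 1, self.n_points)
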