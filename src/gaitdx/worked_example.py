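"""Published worked example: the fitted six-feature diagnostic model.

These constants reproduce the model reported for the original clinical
jogging cohort (25 ACL-deficient legs vs 18 control legs): the fitted
regression coefficients of the optimal six-feature condition (three
phase-summary features plus the first three composite-index features) and
two hypothetical subjects whose feature values sit near their group means.
They serve as a self-contained prediction check: the ACLD subject scores
+0.6164 and the control subject -0.4672, so the sign rule classifies both
correctly.
"""

from __future__ import annotations

import numpy as np

from .regression import DiagnosisModel

FEATURE_NAMES = [
    "mean_stance_force",
    "mean_swing_force",
    "knee_flexion_swing",
    "CI_1",
    "CI_2",
    "CI_3",
]

#: Fitted coefficients: intercept first, then the six features above.
REFERENCE_COEFFICIENTS = np.array(
    [0.1628, 0.2384, -2.5339, 0.7346, -2.3055, -1.5697, 1.2417]
)

#: Coefficient standard errors (intercept first) and two-sided t-test
#: p-values, as reported for the full-sample fit.
REFERENCE_STD_ERRORS = np.array(
    [0.1113, 0.1850, 0.1968, 0.5518, 0.5040, 0.5468, 0.9698]
)
REFERENCE_R_SQUARED = 0.542
REFERENCE_RMSE = 0.73

#: Hypothetical subjects with feature values near their group means.
ACLD_SUBJECT = np.array([-0.1757, -0.0063, -0.0051, -0.1490, -0.0937, -0.0059])
CONTROL_SUBJECT = np.array([0.2440, 0.0088, 0.0071, 0.2069, 0.1301, 0.0082])

ACLD_EXPECTED_OUTCOME = 0.6164
CONTROL_EXPECTED_OUTCOME = -0.4672


def reference_model() -> DiagnosisModel:
    """The published fitted model as a prediction-only :class:`DiagnosisModel`."""
    model = DiagnosisModel.from_coefficients(FEATURE_NAMES, REFERENCE_COEFFICIENTS)
    model.std_errors = REFERENCE_STD_ERRORS.copy()
    model.r_squared = REFERENCE_R_SQUARED
    model.rmse = REFERENCE_RMSE
    return model
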