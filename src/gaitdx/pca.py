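"""Principal component analysis with deterministic new-sample projection.

Covariance PCA (center, no rescaling): the loading matrix holds the
eigenvectors of the sample covariance of the column-centered data, columns
ordered by descending eigenvalue. Implemented via SVD of the centered data
matrix for numerical stability; eigenvalues are singular values squared over
(m - 1).

Sign convention: each loading column is flipped so that its largest-absolute
entry is positive, making fitted models reproducible across platforms (the
SVD sign is otherwise arbitrary).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSignalWarning, GaitdxError, SchemaError

_ZERO_VARIANCE_TOL = 1e-14


@dataclass
class PCAModel:
    """Fitted PCA: column means, orthonormal loadings, eigenvalues.

    ``loadings`` is n x n with columns ordered by descending eigenvalue;
    ``info_content`` is each eigenvalue's share of the total variance.
    """

    column_means: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    column_labels: list[str] = field(default_factory=list)

    @property
    def n_variables(self) -> int:
        return self.column_means.size

    @property
    def info_content(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= _ZERO_VARIANCE_TOL:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    def to_dict(self) -> dict:
        return {
            "column_means": self.column_means.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "column_labels": list(self.column_labels),
            "sign_convention": "largest-abs-entry-positive",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            column_means=np.asarray(d["column_means"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            column_labels=list(d.get("column_labels", [])),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "PCAModel":
        return cls.from_dict(json.loads(s))


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-absolute entry is positive."""
    idx = np.abs(loadings).argmax(axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs


def pca_fit(G, column_labels: list[str] | None = None) -> PCAModel:
    """Fit covariance PCA to an m x n data matrix (m samples, n variables)."""
    G = np.asarray(G, dtype=float)
    if G.ndim != 2:
        raise SchemaError(f"expected a 2-D data matrix, got shape {G.shape}")
    m, n = G.shape
    if m < 2:
        raise GaitdxError(f"PCA needs at least 2 samples, got {m}")
    if not np.isfinite(G).all():
        raise SchemaError("data matrix has missing/non-finite values")
    means = G.mean(axis=0)
    centered = G - means
    total_var = (centered**2).sum() / (m - 1)
    if total_var <= _ZERO_VARIANCE_TOL:
        warnings.warn(
            "constant data matrix: all eigenvalues are 0",
            DegenerateSignalWarning,
            stacklevel=2,
        )
        return PCAModel(means, np.eye(n), np.zeros(n), list(column_labels or []))
    # full_matrices=True so the loading basis spans all n variables even
    # when m - 1 < n (trailing eigenvalues are exactly 0)
    _, s, vt = np.linalg.svd(centered, full_matrices=True)
    eigenvalues = np.zeros(n)
    eigenvalues[: s.size] = s**2 / (m - 1)
    loadings = _fix_signs(vt.T)
    return PCAModel(means, loadings, eigenvalues, list(column_labels or []))


def pca_transform(model: PCAModel, samples, k: int | None = None) -> np.ndarray:
    """Project samples (rows in the training column layout) onto the first
    ``k`` components: scores = (samples - column_means) @ loadings[:, :k]."""
    samples = np.asarray(samples, dtype=float)
    one_dim = samples.ndim == 1
    if one_dim:
        samples = samples[None, :]
    n = model.n_variables
    if samples.shape[1] != n:
        raise SchemaError(
            f"samples have {samples.shape[1]} columns, model expects {n}"
        )
    if k is None:
        k = n
    if not (0 <= k <= n):
        raise SchemaError(f"k must be in 0..{n}, got {k}")
    scores = (samples - model.column_means) @ model.loadings[:, :k]
    return scores[0] if one_dim else scores


def retained_k(model: PCAModel, info_fraction: float = 0.90) -> int:
    """Smallest k whose cumulative information content reaches ``info_fraction``."""
    if not (0.0 < info_fraction <= 1.0):
        raise SchemaError(f"info_fraction must be in (0, 1], got {info_fraction}")
    info = model.info_content
    if info.sum() <= 0:
        warnings.warn(
            "zero total variance: retaining k=1 component",
            DegenerateSignalWarning,
            stacklevel=2,
        )
        return 1
    cum = np.cumsum(info)
    return int(np.searchsorted(cum, info_fraction - 1e-12) + 1)
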