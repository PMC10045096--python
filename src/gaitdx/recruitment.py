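"""Min/max muscle-recruitment solver for small musculoskeletal systems.

Muscle forces during gait are statically indeterminate: the equilibrium
equations ``C f = d`` (moment arms times unknown muscle forces equal the net
joint loads) admit infinitely many solutions. The min/max recruitment
criterion picks the force set that minimizes the largest relative muscle
activation:

    minimize  max_i f_i / N_i
    subject to  C f = d,   0 <= f_i <= N_i

where ``N_i`` is muscle i's strength. This is a linear program in
``(f, epsilon)`` with the epigraph constraints ``f_i <= epsilon * N_i`` and
``epsilon <= 1`` (no muscle may exceed its strength).

The bare minimax LP can leave sub-maximal muscles underdetermined; the
optional refinement pass repeatedly freezes the saturated muscles (those at
``f_i = epsilon * N_i``) at their forces and re-minimizes the maximal
activation of the remainder until nothing changes, yielding a unique,
physiologically graded solution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .errors import InfeasibleProblemError, SchemaError

EQUILIBRIUM_TOL = 1e-8
SATURATION_TOL = 1e-7


@dataclass
class RecruitmentProblem:
    """Equilibrium system C f = d with per-muscle strength bounds N > 0."""

    C: np.ndarray  # n_dof x n_muscles coefficient matrix
    d: np.ndarray  # n_dof known loads
    N: np.ndarray  # n_muscles strengths, all > 0

    def __post_init__(self):
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.d = np.asarray(self.d, dtype=float).ravel()
        self.N = np.asarray(self.N, dtype=float).ravel()
        if self.C.shape != (self.d.size, self.N.size):
            raise SchemaError(
                f"C has shape {self.C.shape}, expected ({self.d.size}, {self.N.size})"
            )
        if (self.N <= 0).any():
            raise SchemaError("all muscle strengths N must be positive")

    @property
    def n_muscles(self) -> int:
        return self.N.size

    @property
    def n_dof(self) -> int:
        return self.d.size

    def to_dict(self) -> dict:
        return {"C": self.C.tolist(), "d": self.d.tolist(), "N": self.N.tolist()}

    @classmethod
    def from_dict(cls, obj: dict) -> "RecruitmentProblem":
        return cls(C=obj["C"], d=obj["d"], N=obj["N"])

    @classmethod
    def from_json(cls, s: str) -> "RecruitmentProblem":
        return cls.from_dict(json.loads(s))


@dataclass
class RecruitmentSolution:
    """Optimal forces, the minimized maximal activation, and the residual."""

    f: np.ndarray
    epsilon: float
    feasible: bool
    residual: float

    def to_dict(self) -> dict:
        return {
            "f": self.f.tolist(),
            "epsilon": self.epsilon,
            "feasible": self.feasible,
            "residual": self.residual,
        }


def _minimax_lp(C, d, N, lower, upper, active=None):
    """min eps s.t. C f = d, lower <= f <= upper, f_i - eps*N_i <= 0 for the
    ``active`` muscles, 0 <= eps <= 1.

    ``lower``/``upper`` allow freezing muscles during refinement; frozen
    muscles drop out of the eps-ratio constraints (``active`` False).
    Returns (f, eps) or None when infeasible.
    """
    n = N.size
    if active is None:
        active = np.ones(n, dtype=bool)
    c = np.zeros(n + 1)
    c[-1] = 1.0
    A_eq = np.hstack([C, np.zeros((C.shape[0], 1))])
    A_ub = np.hstack([np.eye(n), -N[:, None]])[active]
    b_ub = np.zeros(int(active.sum()))
    bounds = [(lo, up) for lo, up in zip(lower, upper)] + [(0.0, 1.0)]
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=d, bounds=bounds, method="highs"
    )
    if not res.success:
        return None
    return res.x[:n], float(res.x[-1])


def solve_minmax(problem: RecruitmentProblem, refine: bool = True) -> RecruitmentSolution:
    """Solve the min/max recruitment LP; optionally refine for uniqueness.

    Raises :class:`InfeasibleProblemError` when no force vector satisfies
    equilibrium within the strength bounds.
    """
    C, d, N = problem.C, problem.d, problem.N
    n = problem.n_muscles
    lower = np.zeros(n)
    upper = N.astype(float).copy()
    out = _minimax_lp(C, d, N, lower, upper)
    if out is None:
        # quantify how badly equilibrium is violated at the least-infeasible point
        f_ls, *_ = np.linalg.lstsq(C, d, rcond=None)
        f_clip = np.clip(f_ls, 0, N)
        violation = float(np.abs(C @ f_clip - d).max())
        raise InfeasibleProblemError(
            "no muscle-force vector satisfies C f = d within 0 <= f <= N "
            f"(best clipped least-squares residual {violation:.3g})",
            violation=violation,
        )
    f, eps = out
    if refine:
        frozen = np.zeros(n, dtype=bool)
        level = eps
        while not frozen.all():
            saturated = (~frozen) & (
                f >= level * N - SATURATION_TOL * np.maximum(N, 1.0)
            )
            if not saturated.any():
                break
            lower[saturated] = f[saturated]
            upper[saturated] = f[saturated]
            frozen |= saturated
            if frozen.all():
                break
            nxt = _minimax_lp(C, d, N, lower, upper, active=~frozen)
            if nxt is None:  # numerically stuck: keep the current solution
                break
            f, level = nxt
        eps = float(np.max(f / N)) if n else 0.0
    residual = float(np.abs(C @ f - d).max()) if problem.n_dof else 0.0
    return RecruitmentSolution(
        f=np.clip(f, 0.0, N), epsilon=float(eps), feasible=True, residual=residual
    )
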