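"""Discrete maximum-entropy solver via the convex Lagrangian dual.

Fits the distribution ``p`` on ``N`` territorial units that maximizes Shannon
entropy ``H(p) = -sum_i p_i ln p_i`` subject to linear expectation constraints

    sum_i p_i g_r(i) = C_r,   r = 1..R,

plus the implicit normalization ``sum_i p_i = 1``.  The unique maximizer has
exponential form ``p_i = exp(-lambda0 - sum_r lambda_r g_r(i))``; the
multipliers are found by minimizing the smooth convex dual

    f(lambda) = ln Z(lambda) + lambda . C,
    Z(lambda) = sum_i exp(-lambda . g(i)),

with a damped Newton iteration.  Constraint rows are rescaled internally to
unit max-absolute-value so that high-order index moments (which reach ``N**m``)
do not wreck the dual Hessian; the returned multipliers are expressed on the
caller's original row scale, so the exponential form holds with the rows as
supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import ConditioningError, ConvergenceError, FeasibilityError

__all__ = [
    "ProbabilityVector",
    "ConstraintSet",
    "SolverOptions",
    "MaxEntSolution",
    "solve_maxent",
    "shannon_entropy",
    "constraint_residuals",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ProbabilityVector:
    """A distribution of population shares over indexed territorial units.

    Parameters
    ----------
    p : array-like of shape (N,)
        Non-negative shares summing to one.
    tu_index : array-like of shape (N,), optional
        1-based unit indices in the current ordering; defaults to ``1..N``.
    """

    p: np.ndarray
    tu_index: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise ValueError("a probability vector needs at least two entries")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise ValueError("shares must be finite and non-negative")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"shares sum to {p.sum():.12g}, not 1")
        idx = self.tu_index
        idx = np.arange(1, p.size + 1) if idx is None else np.asarray(idx, dtype=int)
        if idx.shape != p.shape or len(set(idx.tolist())) != p.size:
            raise ValueError("tu_index must be a permutation-like label vector")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "tu_index", idx)

    @property
    def n(self) -> int:
        return self.p.size

    @classmethod
    def uniform(cls, n: int) -> "ProbabilityVector":
        return cls(np.full(n, 1.0 / n))


@dataclass(frozen=True)
class ConstraintSet:
    """Linear expectation constraints ``G p = C`` (normalization implicit).

    ``G`` and ``C`` are stored exactly as supplied; ``scale`` records the
    per-row factor (max absolute value of the row) the solver divides out
    internally for conditioning.  An empty set (R = 0) is valid and denotes
    the natural restriction only.
    """

    G: np.ndarray
    C: np.ndarray
    labels: tuple[str, ...] = ()
    scale: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        G = np.atleast_2d(np.asarray(self.G, dtype=float))
        C = np.atleast_1d(np.asarray(self.C, dtype=float))
        if G.size == 0:
            G = G.reshape(0, max(G.shape[-1], 2) if G.ndim == 2 else 2)
        R, N = G.shape
        if C.shape != (R,):
            raise ValueError(f"C has shape {C.shape}, expected ({R},)")
        if not np.all(np.isfinite(G)) or not np.all(np.isfinite(C)):
            raise ValueError("constraint rows and targets must be finite")
        labels = tuple(self.labels) if self.labels else tuple(f"r{r+1}" for r in range(R))
        if len(labels) != R:
            raise ValueError("one label per constraint row required")
        if R > 0:
            rowmax = np.max(np.abs(G), axis=1)
            if np.any(rowmax == 0):
                dead = labels[int(np.argmin(rowmax))]
                raise ValueError(f"constraint row {dead!r} is identically zero")
            if R > N - 1:
                raise ValueError(
                    f"{R} constraints on {N} units exceed the N-1 degrees of freedom"
                )
            scale = rowmax
        else:
            scale = np.empty(0)
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "scale", scale)

    @property
    def n_constraints(self) -> int:
        return self.G.shape[0]

    @property
    def n_units(self) -> int:
        return self.G.shape[1]

    @classmethod
    def empty(cls, n_units: int) -> "ConstraintSet":
        return cls(np.empty((0, n_units)), np.empty(0))

    def check_feasible(self, rel_tol: float = 1e-9) -> None:
        """Range test: each target must be attainable by some distribution.

        A target equal to the row minimum or maximum is only reachable by a
        degenerate distribution, which the exponential family excludes, so
        strict interiority is required for non-constant rows.
        """
        for r in range(self.n_constraints):
            row, c = self.G[r], self.C[r]
            lo, hi = row.min(), row.max()
            span = hi - lo
            if span <= rel_tol * max(1.0, abs(hi), abs(lo)):  # constant row
                if abs(c - row[0]) > rel_tol * max(1.0, abs(c)):
                    raise FeasibilityError(
                        f"row {self.labels[r]!r} is constant at {row[0]:.6g} "
                        f"but targets {c:.6g}"
                    )
            elif not (lo < c < hi):
                raise FeasibilityError(
                    f"target {c:.6g} of row {self.labels[r]!r} lies outside the "
                    f"attainable open range ({lo:.6g}, {hi:.6g})"
                )


@dataclass(frozen=True)
class SolverOptions:
    """Numerical settings for the dual Newton iteration.

    tolerance applies to ``max_r |residual_r| / max(1, |C_r|)`` on the
    original row scale.
    """

    tolerance: float = 1e-10
    max_iterations: int = 200
    initial_lambdas: Sequence[float] | None = None
    raise_on_failure: bool = True


@dataclass(frozen=True)
class MaxEntSolution:
    """Solution record: distribution, multipliers and diagnostics.

    ``lambdas`` are expressed against the original (unscaled) rows, so
    ``p_i = exp(-lambda0 - sum_r lambdas[r] * G[r, i])`` holds exactly;
    ``residuals`` are ``sum_i p_i G[r, i] - C_r`` on the original scale.
    """

    p: ProbabilityVector
    lambdas: np.ndarray
    lambda0: float
    entropy: float
    residuals: np.ndarray
    iterations: int
    converged: bool


def shannon_entropy(p: ProbabilityVector | Sequence[float]) -> float:
    """Shannon entropy ``-sum_i p_i ln p_i`` in nats; zero entries contribute 0."""
    if not isinstance(p, ProbabilityVector):
        p = ProbabilityVector(np.asarray(p, dtype=float))
    x = p.p
    nz = x > 0
    return float(-np.sum(x[nz] * np.log(x[nz])))


def constraint_residuals(
    p: ProbabilityVector | Sequence[float], constraints: ConstraintSet
) -> np.ndarray:
    """Per-row constraint violations ``sum_i p_i G[r,i] - C_r`` (original scale)."""
    x = p.p if isinstance(p, ProbabilityVector) else np.asarray(p, dtype=float)
    if x.shape[0] != constraints.n_units:
        raise ValueError(
            f"distribution over {x.shape[0]} units does not match "
            f"{constraints.n_units}-unit constraint set"
        )
    return constraints.G @ x - constraints.C


def _dual_value(lam_s: np.ndarray, Gs: np.ndarray, Cs: np.ndarray) -> float:
    return float(logsumexp(-lam_s @ Gs) + lam_s @ Cs)


def solve_maxent(
    constraints: ConstraintSet, options: SolverOptions | None = None
) -> MaxEntSolution:
    """Solve the constrained maximum-entropy problem.

    Minimizes the convex dual by Newton's method with Armijo backtracking,
    starting from zero multipliers (the uniform distribution).  Deterministic
    for fixed inputs.

    Raises
    ------
    FeasibilityError
        If any target fails the range pre-check.
    ConditioningError
        If the rows are linearly dependent (e.g. duplicated) or the dual
        Hessian becomes numerically singular.
    ConvergenceError
        If the residual tolerance is not met within the iteration budget and
        ``options.raise_on_failure`` is set.
    """
    opts = options or SolverOptions()
    R, N = constraints.n_constraints, constraints.n_units

    if R == 0:
        p = ProbabilityVector.uniform(N)
        return MaxEntSolution(
            p=p,
            lambdas=np.empty(0),
            lambda0=float(np.log(N)),
            entropy=shannon_entropy(p),
            residuals=np.empty(0),
            iterations=0,
            converged=True,
        )

    constraints.check_feasible()

    Gs0 = constraints.G / constraints.scale[:, None]
    Cs0 = constraints.C / constraints.scale
    if np.linalg.matrix_rank(Gs0) < R:
        raise ConditioningError(
            "constraint rows are linearly dependent; remove duplicated or "
            "redundant restrictions"
        )

    # orthonormalize the rows (an invertible recombination of constraints
    # leaves the feasible set, and hence the solution, unchanged) so that the
    # dual Hessian stays well conditioned even for high-order moment rows
    Q, Rm = np.linalg.qr(Gs0.T)
    Gs = Q.T
    Cs = np.linalg.solve(Rm.T, Cs0)

    if opts.initial_lambdas is None:
        lam = np.zeros(R)
    else:
        lam0 = np.asarray(opts.initial_lambdas, dtype=float) * constraints.scale
        lam = Rm @ lam0
    denom = np.maximum(1.0, np.abs(constraints.C))

    p = np.full(N, 1.0 / N)
    iterations = 0
    converged = False
    for iterations in range(1, opts.max_iterations + 1):
        a = -lam @ Gs
        logZ = logsumexp(a)
        p = np.exp(a - logZ)
        Eg = Gs @ p
        resid = constraints.G @ p - constraints.C
        if np.max(np.abs(resid) / denom) <= opts.tolerance:
            converged = True
            break

        grad = Cs - Eg  # gradient of the dual
        H = (Gs * p) @ Gs.T - np.outer(Eg, Eg)
        step = None
        ridge = 0.0
        for _ in range(3):  # escalate Tikhonov damping if the solve fails
            try:
                step = np.linalg.solve(H + ridge * np.eye(R), -grad)
                if np.all(np.isfinite(step)):
                    break
            except np.linalg.LinAlgError:
                pass
            ridge = max(ridge * 1e4, 1e-14 * max(np.trace(H), 1.0))
            step = None
        if step is None:
            raise ConditioningError(
                f"dual Hessian singular at iteration {iterations}; the "
                "constraint set is numerically degenerate"
            )

        f0 = logZ + float(lam @ Cs)
        slope = float(grad @ step)
        # near the optimum the predicted decrease drops below floating-point
        # resolution of the dual value; take the full Newton step then
        if abs(slope) <= 1e-14 * max(1.0, abs(f0)):
            t = 1.0
        else:
            t, best_t, best_f = 1.0, 1.0, np.inf
            for _ in range(60):
                fv = _dual_value(lam + t * step, Gs, Cs)
                if fv <= f0 + 1e-4 * t * slope:
                    best_t = t
                    break
                if fv < best_f:
                    best_f, best_t = fv, t
                t *= 0.5
            t = best_t
        lam = lam + t * step

    a = -lam @ Gs
    logZ = float(logsumexp(a))
    p = np.exp(a - logZ)
    p = p / p.sum()
    resid = constraints.G @ p - constraints.C
    converged = bool(np.max(np.abs(resid) / denom) <= opts.tolerance)

    if not converged and opts.raise_on_failure:
        worst = int(np.argmax(np.abs(resid) / denom))
        raise ConvergenceError(
            f"no convergence in {iterations} iterations; worst-violated row "
            f"{constraints.labels[worst]!r} (residual {resid[worst]:.3g} "
            f"against target {constraints.C[worst]:.6g})"
        )

    pv = ProbabilityVector(p)
    return MaxEntSolution(
        p=pv,
        lambdas=np.linalg.solve(Rm, lam) / constraints.scale,
        lambda0=logZ,
        entropy=shannon_entropy(pv),
        residuals=resid,
        iterations=iterations,
        converged=converged,
    )
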