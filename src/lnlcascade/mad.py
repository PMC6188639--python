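"""MAximum Differentiation (MAD) stimulus synthesis.

Given a reference stimulus and a fixed Euclidean (RMSE) budget, MAD looks
for the stimuli on the sphere ||x − x_A|| = D_E with maximal and minimal
perceptual distance D_P(x, x_A) under a vision model.  Two routes are
provided:

* a sphere-constrained gradient ascent/descent on D_P, where each step
  moves along ±λ·∇D_P, removes the component parallel to the Euclidean
  gradient and solves analytically for the projection constant ν that puts
  the iterate back on the sphere exactly; and
* the analytic second-order solution: the extremal directions are the
  eigenvectors of the metric M(x_A) = J^T J with extremal eigenvalues
  (computed per patch when the metric is block-structured).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Cascade, Stimulus
from .calculus import vjp
from .geometry import metric, perceptual_distance

__all__ = [
    "MADProblem",
    "MADTrace",
    "MADRun",
    "EigenMAD",
    "perceptual_distance_gradient",
    "mad_step",
    "mad_run",
    "eigen_mad",
]


def _vec(x) -> np.ndarray:
    return x.values if isinstance(x, Stimulus) else np.asarray(x, dtype=float)


@dataclass
class MADProblem:
    reference: np.ndarray
    radius: float  # Euclidean distance budget D_E
    step: float | None = None  # gradient step λ; default 0.1·radius/|∇D_P|
    seed: int = 0
    max_iter: int = 300
    stall_tol: float = 1e-8
    stall_patience: int = 20
    patch_deg: float = 0.65  # patch size for the block-metric analytic route

    def __post_init__(self) -> None:
        self.reference = _vec(self.reference)
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class MADTrace:
    distances: np.ndarray  # perceptual distance per accepted iterate
    final: np.ndarray  # extremal stimulus found
    iterates: list[np.ndarray] | None = None
    stalled: bool = False


@dataclass
class MADRun:
    max: MADTrace
    min: MADTrace
    x_init: np.ndarray


def perceptual_distance_gradient(xB, xA, cascade: Cascade) -> np.ndarray:
    """Row-vector gradient of D_P(·, xA) at xB.

    ∇D_P = ((S(xB) − S(xA))^T / D_P) · ∇S(xB); computed as a lazy
    vector-Jacobian product.  Returns zeros (with a warning) when the
    responses coincide and the gradient is undefined.
    """
    xB, xA = _vec(xB), _vec(xA)
    rB = cascade.response(xB)
    rA = cascade.response(xA)
    diff = rB - rA
    dist = np.linalg.norm(diff)
    if dist == 0:
        warnings.warn("zero perceptual distance: gradient undefined, returning 0")
        return np.zeros_like(xB)
    return vjp(cascade, xB, diff / dist)


def _project_to_sphere(
    x_naive: np.ndarray, x_m: np.ndarray, x_ref: np.ndarray, radius: float
) -> np.ndarray | None:
    """Remove the radial component of the step and solve for ν so the new
    point sits on the sphere exactly; None when no real root exists."""
    u = (x_m - x_ref) / np.linalg.norm(x_m - x_ref)
    v = x_naive - x_ref
    radial = float(u @ v)
    t = v - radial * u
    t_norm2 = float(t @ t)
    if t_norm2 >= radius**2:
        return None
    nu = np.sqrt(radius**2 - t_norm2)
    # of the two roots ±ν pick the one nearer the pre-projection point
    if radial < 0:
        nu = -nu
    return x_ref + t + nu * u


def mad_step(
    x_m: np.ndarray,
    problem: MADProblem,
    cascade: Cascade,
    direction: str = "max",
    lam: float | None = None,
) -> tuple[np.ndarray, float]:
    """One sphere-constrained gradient step; returns (x_{m+1}, λ used).

    The step is retried with halved λ until the projection constant ν has a
    real root (i.e. the tangential displacement fits inside the sphere).
    """
    x_m = np.asarray(x_m, dtype=float)
    g = perceptual_distance_gradient(x_m, problem.reference, cascade)
    gnorm = np.linalg.norm(g)
    if gnorm == 0:
        return x_m.copy(), 0.0
    if lam is None:
        lam = problem.step if problem.step is not None else 0.1 * problem.radius / gnorm
    sign = {"max": 1.0, "min": -1.0}[direction]
    for _ in range(60):
        if lam == 0:
            return x_m.copy(), 0.0
        x_next = _project_to_sphere(
            x_m + sign * lam * g, x_m, problem.reference, problem.radius
        )
        if x_next is not None:
            return x_next, lam
        lam *= 0.5
    raise RuntimeError("MAD step failed: no real projection root at any step size")


def _run_one(problem: MADProblem, cascade: Cascade, x_init: np.ndarray,
             direction: str, keep_iterates: bool) -> MADTrace:
    better = (lambda new, old: new > old) if direction == "max" else (
        lambda new, old: new < old
    )
    x = x_init.copy()
    dist = perceptual_distance(x, problem.reference, cascade)
    distances = [dist]
    iterates = [x.copy()] if keep_iterates else None
    lam = problem.step
    stall = 0
    stalled = False
    for _ in range(problem.max_iter):
        accepted = False
        trial_lam = lam
        for _ in range(25):  # backtracking line search on λ
            x_trial, used = mad_step(x, problem, cascade, direction, trial_lam)
            d_trial = perceptual_distance(x_trial, problem.reference, cascade)
            if better(d_trial, dist):
                x, new_dist = x_trial, d_trial
                lam = used * 1.3  # grow the step after a successful move
                accepted = True
                break
            trial_lam = used * 0.5
            if trial_lam < 1e-15:
                break
        if not accepted:
            stalled = True
            break
        rel_change = abs(new_dist - dist) / max(dist, 1e-300)
        dist = new_dist
        distances.append(dist)
        if keep_iterates:
            iterates.append(x.copy())
        stall = stall + 1 if rel_change < problem.stall_tol else 0
        if stall >= problem.stall_patience:
            stalled = True
            break
    return MADTrace(
        distances=np.asarray(distances), final=x, iterates=iterates, stalled=stalled
    )


def mad_run(
    problem: MADProblem, cascade: Cascade, keep_iterates: bool = False
) -> MADRun:
    """Run both the distance-maximizing and -minimizing searches from the
    same seeded white-noise start on the sphere."""
    rng = np.random.default_rng(problem.seed)
    noise = rng.standard_normal(problem.reference.size)
    x_init = problem.reference + problem.radius * noise / np.linalg.norm(noise)
    return MADRun(
        max=_run_one(problem, cascade, x_init, "max", keep_iterates),
        min=_run_one(problem, cascade, x_init, "min", keep_iterates),
        x_init=x_init,
    )


@dataclass
class EigenMAD:
    x_max: np.ndarray  # stimulus in the most-visible direction
    x_min: np.ndarray  # stimulus in the least-visible direction
    lam_max: float
    lam_min: float
    tied: bool = False


def eigen_mad(
    xA,
    cascade: Cascade,
    radius: float,
    patches: list[np.ndarray] | None = None,
    patch_deg: float | None = None,
) -> EigenMAD:
    """Analytic second-order MAD: xA ± radius·v with v the eigenvector of
    M(xA) of extremal eigenvalue.

    In patch mode the metric is block-diagonal, so the global extremal
    eigenvectors are per-patch eigenvectors embedded in the full space; the
    extremum is taken over all patches.  Ties are broken deterministically
    (lowest eigenvalue index / lowest patch) and flagged.
    """
    x = _vec(xA)
    mm = metric(x, cascade, patches=patches, patch_geometry=patch_deg)
    if mm.blocks is None:
        evals, evecs = np.linalg.eigh(mm.M)
        tied = bool(
            np.isclose(evals[0], evals[-1])
            or np.isclose(evals[-1], evals[-2] if evals.size > 1 else evals[-1])
        )
        v_min, v_max = evecs[:, 0], evecs[:, -1]
        lam_min, lam_max = float(evals[0]), float(evals[-1])
    else:
        best = (-np.inf, None)  # (eigenvalue, embedded vector)
        worst = (np.inf, None)
        tied = False
        for idx, blk in mm.blocks:
            evals, evecs = np.linalg.eigh(blk)
            if evals[-1] > best[0]:
                v = np.zeros_like(x)
                v[idx] = evecs[:, -1]
                best = (float(evals[-1]), v)
            if evals[0] < worst[0]:
                v = np.zeros_like(x)
                v[idx] = evecs[:, 0]
                worst = (float(evals[0]), v)
        lam_max, v_max = best
        lam_min, v_min = worst
    if tied:
        warnings.warn("degenerate extremal eigenvalues; deterministic tie-break")
    return EigenMAD(
        x_max=x + radius * v_max,
        x_min=x + radius * v_min,
        lam_max=lam_max,
        lam_min=lam_min,
        tied=tied,
    )
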