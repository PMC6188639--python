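"""Parameter estimation through the analytic parameter Jacobians.

Three differentiable objectives are provided:

* quadratic response matching  ε(Θ) = Σ ||x_exp − S(x⁰, Θ)||²  against
  recorded (or synthetic) responses,
* inverse consistency  ε'(Θ) = Σ ||x⁰ − S^{-1}(x_exp, Θ)||², whose gradient
  uses ∇_Θ S^{-1} = −(∇_{x0}S)^{-1}·∇_Θ S, and
* the Pearson correlation ϱ(Θ) between mean opinion scores and model
  perceptual distances, the indirect-data objective of quality-rating
  psychophysics.

All gradients are exact (finite-difference validated) and the drivers keep
positive parameters positive by optimizing their logarithms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import Cascade, ParameterLayout, unpack_params
from .calculus import jacobian_params, inverse_param_jacobian
from .decoding import cascade_inverse

__all__ = [
    "QualityDataset",
    "FitSchedule",
    "FitTrace",
    "quadratic_cost",
    "quadratic_cost_gradient",
    "inverse_consistency_cost",
    "inverse_consistency_gradient",
    "pearson_objective",
    "pearson_gradient",
    "fit",
]

# parameters kept positive via log-reparameterization inside the optimizers
LOG_PARAMS = ("gamma", "b", "c", "sigma")


@dataclass
class QualityDataset:
    """Originals, distorted versions and mean opinion scores (MOS)."""

    originals: np.ndarray  # (N, d0)
    distorted: np.ndarray  # (N, d0)
    mos: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.originals = np.atleast_2d(np.asarray(self.originals, dtype=float))
        self.distorted = np.atleast_2d(np.asarray(self.distorted, dtype=float))
        self.mos = np.asarray(self.mos, dtype=float).ravel()
        if not (
            len(self.originals) == len(self.distorted) == len(self.mos)
        ):
            raise ValueError("originals, distorted and mos must have equal length")
        if not np.all(np.isfinite(self.distorted)):
            raise ValueError("non-finite distortions")

    def __len__(self) -> int:
        return len(self.mos)

    def subset(self, idx) -> "QualityDataset":
        return QualityDataset(self.originals[idx], self.distorted[idx], self.mos[idx])


# ---------------------------------------------------------------------------
# direct input-output objectives
# ---------------------------------------------------------------------------

def quadratic_cost(cascade: Cascade, x0_batch: np.ndarray,
                   targets: np.ndarray) -> float:
    x0_batch = np.atleast_2d(x0_batch)
    targets = np.atleast_2d(targets)
    return float(
        sum(
            np.sum((t - cascade.response(x)) ** 2)
            for x, t in zip(x0_batch, targets)
        )
    )


def quadratic_cost_gradient(
    cascade: Cascade,
    x0_batch: np.ndarray,
    targets: np.ndarray,
    layout: ParameterLayout,
) -> np.ndarray:
    """∂ε/∂Θ = −2·Σ (x_exp − S(x⁰,Θ))^T · ∇_Θ S."""
    x0_batch = np.atleast_2d(x0_batch)
    targets = np.atleast_2d(targets)
    if len(x0_batch) != len(targets):
        raise ValueError("batch shape mismatch")
    grad = np.zeros(layout.size)
    for x0, target in zip(x0_batch, targets):
        resid = target - cascade.response(x0)
        grad -= 2.0 * resid @ jacobian_params(cascade, x0, layout)
    return grad


def inverse_consistency_cost(
    cascade: Cascade, x0_batch: np.ndarray, responses: np.ndarray
) -> float:
    x0_batch = np.atleast_2d(x0_batch)
    responses = np.atleast_2d(responses)
    return float(
        sum(
            np.sum((x0 - cascade_inverse(r, cascade)) ** 2)
            for x0, r in zip(x0_batch, responses)
        )
    )


def inverse_consistency_gradient(
    cascade: Cascade,
    x0_batch: np.ndarray,
    responses: np.ndarray,
    layout: ParameterLayout,
) -> np.ndarray:
    """Gradient of ε' = Σ ||x⁰ − S^{-1}(x_exp, Θ)||², assembled from the
    stimulus Jacobian, the parameter Jacobian and the analytic inverse."""
    x0_batch = np.atleast_2d(x0_batch)
    responses = np.atleast_2d(responses)
    grad = np.zeros(layout.size)
    for x0, r in zip(x0_batch, responses):
        x0_hat = cascade_inverse(r, cascade)
        Jinv = inverse_param_jacobian(cascade, x0_hat, layout)
        grad -= 2.0 * (x0 - x0_hat) @ Jinv
    return grad


# ---------------------------------------------------------------------------
# indirect data: Pearson correlation with opinion scores
# ---------------------------------------------------------------------------

def _model_distances(cascade: Cascade, ds: QualityDataset) -> np.ndarray:
    return np.array(
        [
            np.linalg.norm(cascade.response(z) - cascade.response(x))
            for x, z in zip(ds.originals, ds.distorted)
        ]
    )


def pearson_objective(cascade: Cascade, dataset: QualityDataset) -> float:
    """Pearson correlation between MOS and model perceptual distances."""
    if len(dataset) < 3:
        raise ValueError("need at least 3 items for a meaningful correlation")
    D = _model_distances(cascade, dataset)
    Ms = dataset.mos - dataset.mos.mean()
    Ds = D - D.mean()
    nM, nD = np.linalg.norm(Ms), np.linalg.norm(Ds)
    if nM == 0 or nD == 0:
        raise ValueError("zero variance in MOS or model distances")
    return float(Ms @ Ds / (nM * nD))


def pearson_gradient(
    cascade: Cascade, dataset: QualityDataset, layout: ParameterLayout
) -> np.ndarray:
    """∂ϱ/∂Θ via the chain of centering, normalization and the per-item
    distance derivatives (Δx^n)^T/|Δx^n| · [∇_Θ S(z) − ∇_Θ S(x)].

    Items whose response difference is exactly zero carry an undefined
    distance derivative and are dropped with a warning.
    """
    D = _model_distances(cascade, dataset)
    keep = D > 0
    if not np.all(keep):
        warnings.warn(f"dropping {np.sum(~keep)} item(s) with zero response difference")
        dataset = dataset.subset(keep)
        D = D[keep]
    N = len(dataset)
    Ms = dataset.mos - dataset.mos.mean()
    Ds = D - D.mean()
    nM, nD = np.linalg.norm(Ms), np.linalg.norm(Ds)
    # ∂ϱ/∂Ds, then ∂Ds/∂D = centering matrix
    dr_dDs = Ms / (nM * nD) - (Ms @ Ds) * Ds / (nM * nD**3)
    dr_dD = dr_dDs - dr_dDs.mean()
    rows = np.empty((N, layout.size))
    for c in range(N):
        x, z = dataset.originals[c], dataset.distorted[c]
        diff = cascade.response(z) - cascade.response(x)
        rows[c] = (diff / D[c]) @ (
            jacobian_params(cascade, z, layout) - jacobian_params(cascade, x, layout)
        )
    return dr_dD @ rows


# ---------------------------------------------------------------------------
# optimization drivers
# ---------------------------------------------------------------------------

@dataclass
class FitSchedule:
    method: str = "gd"  # "gd" (fixed-step with backtracking) or "lbfgs"
    n_iter: int = 100
    step: float = 1e-2
    batch_size: int | None = None  # None = full batch; 48 mirrors phase-one SGD
    seed: int = 0
    patience: int = 20  # early stopping on the held-out objective
    store_theta: bool = False


@dataclass
class FitTrace:
    objectives: list[float] = field(default_factory=list)
    test_objectives: list[float] = field(default_factory=list)
    theta: np.ndarray | None = None  # final packed parameters
    theta_history: list[np.ndarray] = field(default_factory=list)
    seed: int = 0
    n_evals: int = 0


def _log_mask(layout: ParameterLayout) -> np.ndarray:
    mask = np.zeros(layout.size, dtype=bool)
    for e in layout.entries:
        if e.name in LOG_PARAMS:
            mask[e.offset : e.offset + e.length] = True
    return mask


def _to_working(theta: np.ndarray, mask: np.ndarray) -> np.ndarray:
    w = theta.copy()
    w[mask] = np.log(theta[mask])
    return w


def _from_working(w: np.ndarray, mask: np.ndarray) -> np.ndarray:
    theta = w.copy()
    theta[mask] = np.exp(w[mask])
    return theta


def fit(
    cascade: Cascade,
    data,
    layout: ParameterLayout,
    objective: str = "quadratic",
    schedule: FitSchedule | None = None,
    test_data=None,
) -> FitTrace:
    """Seeded gradient-based parameter search.

    ``objective``: "quadratic" / "inverse" / "joint" expect
    ``data = (x0_batch, responses)``; "pearson" expects a
    :class:`QualityDataset` and is maximized.  Positive parameters (γ, b, c,
    σ) are optimized in log space.  ``method='gd'`` is plain (optionally
    mini-batched) gradient ascent/descent with backtracking; ``'lbfgs'``
    wraps a quasi-Newton minimizer around the same analytic gradients.
    """
    schedule = schedule or FitSchedule()
    rng = np.random.default_rng(schedule.seed)
    maximize = objective == "pearson"

    def split(batch_idx=None):
        if objective == "pearson":
            return data if batch_idx is None else data.subset(batch_idx)
        x0b, resp = data
        if batch_idx is None:
            return np.atleast_2d(x0b), np.atleast_2d(resp)
        return np.atleast_2d(x0b)[batch_idx], np.atleast_2d(resp)[batch_idx]

    def value(d) -> float:
        if objective == "pearson":
            return pearson_objective(cascade, d)
        x0b, resp = d
        if objective == "quadratic":
            return quadratic_cost(cascade, x0b, resp)
        if objective == "inverse":
            return inverse_consistency_cost(cascade, x0b, resp)
        if objective == "joint":
            return quadratic_cost(cascade, x0b, resp) + inverse_consistency_cost(
                cascade, x0b, resp
            )
        raise ValueError(f"unknown objective {objective!r}")

    def gradient(d) -> np.ndarray:
        if objective == "pearson":
            return pearson_gradient(cascade, d, layout)
        x0b, resp = d
        if objective == "quadratic":
            return quadratic_cost_gradient(cascade, x0b, resp, layout)
        if objective == "inverse":
            return inverse_consistency_gradient(cascade, x0b, resp, layout)
        return quadratic_cost_gradient(
            cascade, x0b, resp, layout
        ) + inverse_consistency_gradient(cascade, x0b, resp, layout)

    theta = np.concatenate(
        [
            cascade.layers[e.layer].linear.L.ravel()
            if e.name == "L"
            else np.atleast_1d(cascade.layers[e.layer].nonlin.get_param(e.name))
            for e in layout.entries
        ]
    ) if layout.entries else np.empty(0)
    mask = _log_mask(layout)
    trace = FitTrace(seed=schedule.seed)

    def set_theta(th):
        unpack_params(th, layout, cascade)

    if schedule.method == "lbfgs":
        sign = -1.0 if maximize else 1.0

        def fun(w):
            th = _from_working(w, mask)
            set_theta(th)
            trace.n_evals += 1
            f = sign * value(split())
            g = sign * gradient(split())
            g = g.copy()
            g[mask] *= th[mask]  # chain rule of the log transform
            return f, g

        res = optimize.minimize(
            fun,
            _to_working(theta, mask),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": schedule.n_iter},
        )
        theta = _from_working(res.x, mask)
        set_theta(theta)
        trace.objectives.append(sign * res.fun)
        trace.theta = theta
        return trace

    # plain gradient ascent/descent
    step = schedule.step
    best_test = -np.inf if maximize else np.inf
    since_best = 0
    full = split()
    current = value(full)
    trace.objectives.append(current)
    if test_data is not None:
        t0 = value(test_data) if objective != "pearson" else pearson_objective(
            cascade, test_data
        )
        trace.test_objectives.append(t0)
        best_test = t0
    if schedule.store_theta:
        trace.theta_history.append(theta.copy())
    direction = 1.0 if maximize else -1.0
    for _ in range(schedule.n_iter):
        if schedule.batch_size is not None:
            nset = len(data) if objective == "pearson" else len(np.atleast_2d(data[0]))
            idx = rng.choice(nset, size=min(schedule.batch_size, nset), replace=False)
            batch = split(idx)
        else:
            batch = full
        g = gradient(batch)
        w = _to_working(theta, mask)
        gw = g.copy()
        gw[mask] *= theta[mask]
        accepted = False
        local = step
        for _ in range(20):
            w_trial = w + direction * local * gw
            th_trial = _from_working(w_trial, mask)
            set_theta(th_trial)
            trial = value(full)
            trace.n_evals += 1
            if not np.isfinite(trial):
                set_theta(theta)
                raise FloatingPointError("objective diverged to non-finite value")
            stochastic = schedule.batch_size is not None
            if stochastic or (trial > current if maximize else trial < current):
                theta, current = th_trial, trial
                if not stochastic:
                    step = local * 1.5  # grow the step after an accepted move
                accepted = True
                break
            local *= 0.5
        if not accepted:
            set_theta(theta)
            break
        trace.objectives.append(current)
        if schedule.store_theta:
            trace.theta_history.append(theta.copy())
        if test_data is not None:
            t = pearson_objective(cascade, test_data) if objective == "pearson" else (
                value(test_data)
            )
            trace.test_objectives.append(t)
            improved = t > best_test if maximize else t < best_test
            if improved:
                best_test, since_best = t, 0
            else:
                since_best += 1
                if since_best >= schedule.patience:
                    break
    set_theta(theta)
    trace.theta = theta
    return trace
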