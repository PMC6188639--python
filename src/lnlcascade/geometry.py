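"""Perceptual distance, the induced metric, sensitivity maps and
multi-information reduction.

Perceived difference between stimuli is modelled as the Euclidean distance
between their responses, D_P(xA, xB) = ||S(xA) − S(xB)||₂.  To second order
this equals sqrt(Δx^T M Δx) with the (stimulus-dependent) metric

    M(xA) = ∇S(xA)^T · ∇S(xA),

whose determinant is inversely proportional to the volume of the
just-noticeable-difference region: det M is used as a scalar *sensitivity*.
The coding-efficiency side is the multi-information reduction of the
transform,

    ΔMI = Σ h(x⁰_k) − Σ h(x^n_k) + E[log₂|det ∇S|],

estimated from samples with histogram marginal entropies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Cascade, ParameterLayout, ParamEntry, Stimulus
from .calculus import jacobian_stimulus, jacobian_params

__all__ = [
    "MetricMatrix",
    "InfoReport",
    "perceptual_distance",
    "metric",
    "sensitivity",
    "marginal_entropy",
    "delta_multi_information",
    "filter_uncertainty_impact",
]


@dataclass
class MetricMatrix:
    """Second-order perceptual metric; optionally block (patch) structured."""

    M: np.ndarray | None  # dense d0 x d0 metric, or None in patch mode
    anchor: np.ndarray
    blocks: list[tuple[np.ndarray, np.ndarray]] | None = None  # (indices, block)
    patch_geometry: float | None = None  # patch size in deg when block mode

    def dense(self) -> np.ndarray:
        if self.M is not None:
            return self.M
        d = self.anchor.size
        out = np.zeros((d, d))
        for idx, blk in self.blocks:
            out[np.ix_(idx, idx)] = blk
        return out


def _as_vec(x) -> np.ndarray:
    return x.values if isinstance(x, Stimulus) else np.asarray(x, dtype=float)


def perceptual_distance(xA, xB, cascade: Cascade) -> float:
    """Euclidean distance between responses; zero iff the responses agree."""
    return float(
        np.linalg.norm(cascade.response(_as_vec(xA)) - cascade.response(_as_vec(xB)))
    )


def metric(xA, cascade: Cascade, patches: list[np.ndarray] | None = None,
           patch_geometry: float | None = None) -> MetricMatrix:
    """M(xA) = J^T J with J = ∇_{x0}S(xA); symmetric positive semidefinite.

    With ``patches`` (a partition of the input indices) only the diagonal
    blocks M[p, p] are kept - the block-diagonal approximation that treats
    distortions in distinct patches as perceptually independent.
    """
    x = _as_vec(xA)
    J = jacobian_stimulus(cascade, x)
    if patches is None:
        M = J.T @ J
        M = 0.5 * (M + M.T)
        return MetricMatrix(M=M, anchor=x)
    blocks = []
    for idx in patches:
        idx = np.asarray(idx, dtype=int)
        Jp = J[:, idx]
        blk = Jp.T @ Jp
        blocks.append((idx, 0.5 * (blk + blk.T)))
    return MetricMatrix(M=None, anchor=x, blocks=blocks, patch_geometry=patch_geometry)


def sensitivity(xA, cascade: Cascade) -> float:
    """det M(xA) = |∇S|²; inverse volume of the discrimination region.

    For rectangular Jacobians this is the Gram determinant det(J^T J), which
    reduces to |det J|² in the square case.  Rank-deficient Jacobians yield 0
    (with a warning).
    """
    J = jacobian_stimulus(cascade, _as_vec(xA))
    M = J.T @ J
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn("rank-deficient Jacobian: sensitivity reported as 0")
        return 0.0
    return float(np.exp(logdet))


def marginal_entropy(samples: np.ndarray, bins: int | None = None) -> float:
    """Differential entropy (bits) of a scalar sample via an equal-width
    histogram with Miller-Madow bias correction."""
    samples = np.asarray(samples, dtype=float).ravel()
    n = samples.size
    if bins is None:
        bins = max(2, int(np.ceil(n ** (1 / 3))))
    counts, edges = np.histogram(samples, bins=bins)
    width = edges[1] - edges[0]
    p = counts[counts > 0] / n
    h_discrete = -np.sum(p * np.log2(p)) + (p.size - 1) / (2 * n * np.log(2))
    if width <= 0:
        return -np.inf  # degenerate (constant) variable
    return float(h_discrete + np.log2(width))


@dataclass
class InfoReport:
    """ΔMI decomposition: delta_MI = delta_h + jac_term by construction."""

    delta_h: float
    jac_term: float
    n_samples: int
    bins: int
    n_dropped: int = 0
    delta_MI: float = field(init=False)

    def __post_init__(self) -> None:
        self.delta_MI = self.delta_h + self.jac_term


def delta_multi_information(
    cascade: Cascade, samples: np.ndarray, bins: int | None = None
) -> InfoReport:
    """Multi-information reduction of the cascade over a sample ensemble.

    ``samples`` is (n, d0); the cascade must preserve dimension so that the
    Jacobian determinant is defined.  Samples at which the Jacobian is
    singular are dropped and counted.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n, d0 = samples.shape
    dims = cascade.dims
    if dims[-1] != d0:
        raise ValueError("ΔMI requires a square (dimension-preserving) cascade")
    if bins is None:
        bins = max(2, int(np.ceil(n ** (1 / 3))))
    responses = np.empty((n, dims[-1]))
    logdets = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        states = cascade.forward(samples[i])
        responses[i] = states[-1].x
        J = jacobian_stimulus(cascade, samples[i])
        sign, logdet = np.linalg.slogdet(J)
        if sign == 0 or not np.isfinite(logdet):
            keep[i] = False
        else:
            logdets[i] = logdet / np.log(2)
    n_dropped = int(np.sum(~keep))
    if n_dropped == n:
        raise ValueError("Jacobian singular at every sample; ΔMI undefined")
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} sample(s) with singular Jacobian")
    h_in = sum(marginal_entropy(samples[keep, k], bins) for k in range(d0))
    h_out = sum(marginal_entropy(responses[keep, k], bins) for k in range(dims[-1]))
    return InfoReport(
        delta_h=h_in - h_out,
        jac_term=float(np.mean(logdets[keep])),
        n_samples=int(np.sum(keep)),
        bins=bins,
        n_dropped=n_dropped,
    )


def filter_uncertainty_impact(
    cascade: Cascade,
    layer: int,
    filter_row: int,
    perturbation: np.ndarray,
    samples: np.ndarray,
) -> np.ndarray:
    """Response change caused by perturbing one row of a layer's linear stage.

    ``perturbation`` is the row increment ΔL_k added to row ``filter_row`` of
    L^layer; the returned array is (n_samples, d_n) with the predicted
    first-order response change ∇_L S · vect(ΔL) per sample.  For the cartoon
    model this reproduces the closed-form per-sensor impact of uncertainty in
    a frequency-analyzer filter.
    """
    if not 0 <= layer < cascade.n:
        raise IndexError(f"layer index {layer} out of range")
    lay = cascade.layers[layer]
    d_out, d_in = lay.linear.L.shape
    perturbation = np.asarray(perturbation, dtype=float).ravel()
    if perturbation.size != d_in:
        raise ValueError(f"perturbation must have length {d_in}")
    if not 0 <= filter_row < d_out:
        raise IndexError(f"filter row {filter_row} out of range")
    layout = ParameterLayout(
        entries=[ParamEntry(layer, "L", 0, d_out * d_in, True)]
    )
    dL = np.zeros((d_out, d_in))
    dL[filter_row] = perturbation
    vec_dL = dL.ravel(order="C")
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    out = np.empty((samples.shape[0], cascade.dims[-1]))
    for i, x0 in enumerate(samples):
        JL = jacobian_params(cascade, x0, layout)
        out[i] = JL @ vec_dL
    return out
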