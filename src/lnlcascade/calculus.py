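"""Chain-rule assembly of the global cascade Jacobians.

The Jacobian of the cascade response with respect to the stimulus is the
ordered product of per-layer pieces,

    ∇_{x0} S = ∏_{i=n..1} ∇_{y^i}N^(i) · L^i      (left-most = last layer)

and the Jacobian with respect to the full parameter vector Θ concatenates,
per layer and per parameter, the local derivative propagated through the
remaining layers.  For the linear stage the local derivative uses the
block-replication identity B(v^T)_d · vect(ΔL^T) = ΔL·v, with matrix
perturbations flattened row-wise.

A central finite-difference oracle is included as the independent check every
analytic Jacobian in the package is validated against.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .core import Cascade, LayerState, ParameterLayout, Stimulus

__all__ = [
    "block_replicator",
    "layer_jacobians",
    "jacobian_stimulus",
    "jacobian_params",
    "inverse_param_jacobian",
    "vjp",
    "fd_oracle",
]


def block_replicator(v: np.ndarray, d: int) -> np.ndarray:
    """B(v^T)_d: block-diagonal matrix with d copies of the row vector v^T.

    Satisfies B(v^T)_d @ ΔL.ravel() == ΔL @ v for any (d, len(v)) matrix ΔL
    flattened row-wise.
    """
    v = np.asarray(v, dtype=float).ravel()
    return np.kron(np.eye(d), v[None, :])


def _states(cascade: Cascade, x0) -> tuple[np.ndarray, list[LayerState]]:
    x = x0.values if isinstance(x0, Stimulus) else np.asarray(x0, dtype=float)
    return x, cascade.forward(x)


def layer_jacobians(cascade: Cascade, states: list[LayerState]) -> list[np.ndarray]:
    """Per-layer ∇_{x^{i-1}}S^(i) = ∇_{y^i}N^(i) · L^i at the forward states."""
    out = []
    for i, (lay, st) in enumerate(zip(cascade.layers, states)):
        try:
            out.append(lay.nonlin.jacobian(st.y) @ lay.linear.L)
        except Exception as exc:
            raise RuntimeError(f"Jacobian failed at layer {i + 1}: {exc}") from exc
    return out


def jacobian_stimulus(cascade: Cascade, x0) -> np.ndarray:
    """Global ∇_{x0}S as the ordered product of per-layer Jacobians."""
    _, states = _states(cascade, x0)
    pieces = layer_jacobians(cascade, states)
    J = pieces[0]
    for piece in pieces[1:]:
        J = piece @ J
    return J


def _suffix_products(pieces: list[np.ndarray], dims: tuple[int, ...]) -> list[np.ndarray]:
    """P_i = ∇S^(n)···∇S^(i+1) for i = 0..n (P_n = identity)."""
    n = len(pieces)
    prods = [np.eye(dims[-1])]
    acc = prods[0]
    for i in range(n - 1, 0, -1):
        acc = acc @ pieces[i]
        prods.append(acc)
    prods.reverse()  # prods[i] multiplies derivatives taken inside layer i+1
    return prods


def jacobian_params(
    cascade: Cascade, x0, layout: ParameterLayout
) -> np.ndarray:
    """Global ∇_Θ S for the parameters selected by ``layout``.

    Per entry (layer i, parameter p) the block is
    [∏_{l=n..i+1} ∇S^(l)] · ∇_p S^(i), where ∇_L S^(i) uses the block
    replicator of x^{i-1} and nonlinearity parameters their own analytic
    Jacobians.
    """
    x_in, states = _states(cascade, x0)
    pieces = layer_jacobians(cascade, states)
    prods = _suffix_products(pieces, cascade.dims)
    d_n = cascade.dims[-1]
    J = np.empty((d_n, layout.size))
    for e in layout.entries:
        i = e.layer
        lay = cascade.layers[i]
        x_prev = x_in if i == 0 else states[i - 1].x
        P = prods[i]  # d_n x d_i, identity for the last layer
        if e.name == "L":
            A = P @ lay.nonlin.jacobian(states[i].y)  # d_n x d_i
            block = np.einsum("ok,j->okj", A, x_prev).reshape(d_n, -1)
        else:
            block = P @ lay.nonlin.jacobian_param(states[i].y, e.name)
        if block.shape != (d_n, e.length):
            raise ValueError(
                f"layout mismatch for layer {i} param {e.name!r}: "
                f"got {block.shape}, expected {(d_n, e.length)}"
            )
        J[:, e.offset : e.offset + e.length] = block
    return J


def inverse_param_jacobian(
    cascade: Cascade, x0, layout: ParameterLayout
) -> np.ndarray:
    """∇_Θ S^{-1} = −(∇_{x0}S)^{-1} · ∇_Θ S (square invertible cascades).

    The identity follows from differentiating S^{-1}(S(x0, Θ), Θ) = x0 with
    respect to Θ.
    """
    Jx = jacobian_stimulus(cascade, x0)
    if Jx.shape[0] != Jx.shape[1]:
        raise ValueError("stimulus Jacobian must be square")
    Jt = jacobian_params(cascade, x0, layout)
    return -np.linalg.solve(Jx, Jt)


def vjp(cascade: Cascade, x0, v: np.ndarray) -> np.ndarray:
    """Lazy vector-Jacobian product v^T · ∇_{x0}S without forming the full
    product of per-layer matrices (used by the MAD gradient at image scale)."""
    _, states = _states(cascade, x0)
    w = np.asarray(v, dtype=float)
    for lay, st in zip(reversed(cascade.layers), reversed(states)):
        w = lay.linear.L.T @ (lay.nonlin.jacobian(st.y).T @ w)
    return w


def fd_oracle(
    func: Callable[[np.ndarray], np.ndarray],
    point: np.ndarray,
    step: float | np.ndarray | None = None,
) -> np.ndarray:
    """Central-difference Jacobian of ``func`` at ``point``.

    The default step is 1e-6·max(1, |coordinate|) per input dimension.
    Intentionally independent of every analytic expression it validates.
    """
    point = np.asarray(point, dtype=float)
    if step is None:
        step = 1e-6 * np.maximum(1.0, np.abs(point))
    h = np.broadcast_to(np.asarray(step, dtype=float), point.shape).copy()
    if np.any(h <= 0) or np.any(point + h == point):
        raise ValueError("finite-difference step underflow")
    cols = []
    for j in range(point.size):
        dx = np.zeros_like(point)
        dx[j] = h[j]
        cols.append(
            (np.atleast_1d(func(point + dx)) - np.atleast_1d(func(point - dx)))
            / (2 * h[j])
        )
    return np.column_stack(cols)
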