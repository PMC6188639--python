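"""Canonical divisive normalization in matrix form.

The nonlinearity is, component-wise,

    x_k = sign(y_k) |y_k|^γ / (b_k + Σ_k' H_kk' |y_k'|^γ)

or, with the energy e = |y|^γ and denominator D(e) = b + H·e, in matrix form

    x = D_sign(y) · D_{D(e)}^{-1} · e.

This module provides the forward map, the analytic Jacobians with respect to
the input and to every parameter (γ, b, H, and the Gaussian-kernel
parameterization of H through per-sensor amplitudes c and widths σ), and the
analytic inverse

    y = D_sign(x) · [(I − D_|x|·H)^{-1} · D_b · |x|]^{1/γ},

which exists whenever the spectral radius of D_|x|·H is below one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Nonlinearity

__all__ = [
    "GaussianKernelSpec",
    "DivNormParams",
    "DivisiveNorm",
    "build_gaussian_H",
    "gaussian_H_dsigma",
    "gaussian_H_dc",
    "dn_forward",
    "dn_jacobian_stimulus",
    "dn_jacobian_params",
    "dn_jacobian_kernel_params",
    "dn_inverse",
    "dn_invertibility_margin",
]


@dataclass
class GaussianKernelSpec:
    """Gaussian parameterization of the interaction kernel H.

    Each row of H is a Gaussian centred on the corresponding sensor:

        H_kk' = c_k · dp / (2π σ_k²) · exp(−Δ_kk'² / 2σ_k²)   (same subband)
        H_kk' = 0                                              (across subbands)

    so the total inhibitory pool of sensor k is Σ_k' H_kk' ≈ c_k on grids
    fine relative to σ.  ``structure_sigma`` / ``structure_c`` are optional
    binary (d × p) matrices tying sensors to shared parameters (e.g. one σ per
    subband); per-sensor values are then ``structure @ params``.
    """

    positions: np.ndarray  # (d, 2) sensor locations in deg
    subband: np.ndarray  # (d,) integer subband labels
    sigma: np.ndarray  # (p_sigma,) widths in deg
    c: np.ndarray  # (p_c,) amplitudes
    dp: float  # grid cell area in deg^2
    structure_sigma: np.ndarray | None = None  # (d, p_sigma) binary
    structure_c: np.ndarray | None = None  # (d, p_c) binary

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.subband = np.asarray(self.subband, dtype=int).ravel()
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        d = self.positions.shape[0]
        if self.structure_sigma is None and self.sigma.size != d:
            raise ValueError("sigma must be per-sensor when no structure matrix given")
        if self.structure_c is None and self.c.size != d:
            raise ValueError("c must be per-sensor when no structure matrix given")
        if np.any(self.sigma <= 0) or self.dp <= 0:
            raise ValueError("sigma and dp must be positive")

    @property
    def d(self) -> int:
        return self.positions.shape[0]

    def sigma_per_sensor(self) -> np.ndarray:
        if self.structure_sigma is None:
            return self.sigma
        return self.structure_sigma @ self.sigma

    def c_per_sensor(self) -> np.ndarray:
        if self.structure_c is None:
            return self.c
        return self.structure_c @ self.c


def _sq_distances(spec: GaussianKernelSpec) -> np.ndarray:
    diff = spec.positions[:, None, :] - spec.positions[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _subband_mask(spec: GaussianKernelSpec) -> np.ndarray:
    return spec.subband[:, None] == spec.subband[None, :]


def build_gaussian_H(spec: GaussianKernelSpec) -> np.ndarray:
    """Materialize H from the Gaussian kernel spec (intra-subband support)."""
    sig = spec.sigma_per_sensor()[:, None]
    amp = spec.c_per_sensor()[:, None]
    d2 = _sq_distances(spec)
    H = amp * spec.dp / (2 * np.pi * sig**2) * np.exp(-d2 / (2 * sig**2))
    H[~_subband_mask(spec)] = 0.0
    return H


def gaussian_H_dsigma(spec: GaussianKernelSpec) -> np.ndarray:
    """Per-sensor ∂H_kk'/∂σ_k (the 'F kernel'); row k varies with σ_k only."""
    sig = spec.sigma_per_sensor()[:, None]
    amp = spec.c_per_sensor()[:, None]
    d2 = _sq_distances(spec)
    F = amp * spec.dp / (2 * np.pi * sig**5) * (d2 - 2 * sig**2) * np.exp(
        -d2 / (2 * sig**2)
    )
    F[~_subband_mask(spec)] = 0.0
    return F


def gaussian_H_dc(spec: GaussianKernelSpec) -> np.ndarray:
    """Per-sensor ∂H_kk'/∂c_k = H_kk'/c_k (the 'G kernel')."""
    sig = spec.sigma_per_sensor()[:, None]
    d2 = _sq_distances(spec)
    G = spec.dp / (2 * np.pi * sig**2) * np.exp(-d2 / (2 * sig**2))
    G[~_subband_mask(spec)] = 0.0
    return G


@dataclass
class DivNormParams:
    """Parameter bundle {γ, b, H} of one divisive-normalization stage."""

    gamma: float
    b: np.ndarray
    H: np.ndarray | None = None
    kernel_spec: GaussianKernelSpec | None = None
    # |y| floor used only inside the stimulus Jacobian when γ < 1 (the
    # |y|^{γ-1} factor diverges at 0); mirrors the quadratic patch philosophy
    # of the two-gamma model.
    eta: float = 1e-6

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if np.any(self.b <= 0):
            raise ValueError("semisaturation b must be strictly positive")
        if self.gamma <= 0:
            raise ValueError("exponent gamma must be positive")
        if self.H is None and self.kernel_spec is None:
            raise ValueError("either H or kernel_spec must be given")
        if self.H is not None:
            self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
            if np.any(self.H < 0) or not np.all(np.isfinite(self.H)):
                raise ValueError("H must be finite and nonnegative")

    def interaction(self) -> np.ndarray:
        return self.H if self.H is not None else build_gaussian_H(self.kernel_spec)


def _energy(y: np.ndarray, gamma: float) -> np.ndarray:
    return np.abs(y) ** gamma


def dn_forward(y: np.ndarray, p: DivNormParams) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    e = _energy(y, p.gamma)
    D = p.b + p.interaction() @ e
    return np.sign(y) * e / D


def dn_jacobian_stimulus(y: np.ndarray, p: DivNormParams) -> np.ndarray:
    """Jacobian of the DN response with respect to its input y.

    J = D_sign · D_{D(e)}^{-1} · [I − D_{e/D} · H] · D_{γ|y|^{γ-1}} · D_sign.
    Diagonal when H is diagonal; for γ < 1 the |y|^{γ-1} factor is evaluated
    with |y| floored at ``p.eta``.
    """
    y = np.asarray(y, dtype=float)
    d = y.size
    H = p.interaction()
    e = _energy(y, p.gamma)
    D = p.b + H @ e
    ay = np.abs(y)
    if p.gamma < 1:
        ay = np.maximum(ay, p.eta)
    g = p.gamma * ay ** (p.gamma - 1)
    s = np.sign(y)
    inner = np.eye(d) - (e / D)[:, None] * H
    return (s / D)[:, None] * inner * (g * s)[None, :]


def dn_jacobian_params(
    y: np.ndarray, p: DivNormParams
) -> dict[str, np.ndarray]:
    """Analytic Jacobians of the DN response w.r.t. γ (d×1), b (d×d,
    diagonal) and H (d×d², row-wise vectorization of the perturbation)."""
    y = np.asarray(y, dtype=float)
    d = y.size
    H = p.interaction()
    e = _energy(y, p.gamma)
    D = p.b + H @ e
    s = np.sign(y)
    if np.any(y == 0):
        raise ValueError("gamma derivative undefined at y_k = 0 (log|y| singular)")
    loga = np.log(np.abs(y))
    grad_gamma = (s / D) * (loga * e - (H @ (e * loga)) * e / D)
    grad_b = np.diag(-s * e / D**2)
    # row k of ∇_H N is −s_k e_k / D_k² · e^T placed in the k-th d-block
    pref = -s * e / D**2
    grad_H = np.zeros((d, d * d))
    for k in range(d):
        grad_H[k, k * d : (k + 1) * d] = pref[k] * e
    return {"gamma": grad_gamma[:, None], "b": grad_b, "H": grad_H}


def dn_jacobian_kernel_params(
    y: np.ndarray, p: DivNormParams
) -> dict[str, np.ndarray]:
    """Jacobians w.r.t. the Gaussian-kernel widths σ and amplitudes c.

    Per sensor these are diagonal (σ_k and c_k parameterize row k of H only):
    ∂x_k/∂σ_k = −sign_k e_k/D_k² · (F·e)_k with F = ∂H/∂σ, and analogously
    with G = H/c for the amplitudes.  When the spec carries structure
    matrices the columns are pooled by right-multiplication with them.
    """
    if p.kernel_spec is None:
        raise ValueError("kernel_spec required for kernel-parameter Jacobians")
    spec = p.kernel_spec
    y = np.asarray(y, dtype=float)
    H = p.interaction()
    e = _energy(y, p.gamma)
    D = p.b + H @ e
    pref = -np.sign(y) * e / D**2
    grad_sigma = np.diag(pref * (gaussian_H_dsigma(spec) @ e))
    grad_c = np.diag(pref * (gaussian_H_dc(spec) @ e))
    if spec.structure_sigma is not None:
        grad_sigma = grad_sigma @ spec.structure_sigma
    if spec.structure_c is not None:
        grad_c = grad_c @ spec.structure_c
    return {"sigma": grad_sigma, "c": grad_c}


def dn_invertibility_margin(x: np.ndarray, p: DivNormParams) -> float:
    """Spectral radius of D_|x|·H; the inverse exists iff it is below 1."""
    A = np.abs(np.asarray(x, dtype=float))[:, None] * p.interaction()
    return float(np.max(np.abs(np.linalg.eigvals(A)))) if A.size else 0.0


def dn_inverse(
    x: np.ndarray,
    p: DivNormParams,
    method: str = "direct",
    order: int = 10,
    residual_tol: float = 1e-8,
) -> np.ndarray:
    """Analytic inverse of divisive normalization.

    ``direct`` solves the linear system (I − D_|x|·H)·v = D_b·|x|; ``series``
    replaces the matrix inversion by a truncated Neumann expansion (order
    matrix-on-vector products) with an a-posteriori residual check.
    """
    x = np.asarray(x, dtype=float)
    H = p.interaction()
    ax = np.abs(x)
    radius = dn_invertibility_margin(x, p)
    if radius >= 1:
        raise np.linalg.LinAlgError(
            f"divisive normalization not invertible: spectral radius "
            f"of D_|x|.H is {radius:.4f} >= 1"
        )
    rhs = p.b * ax
    A = ax[:, None] * H
    if method == "direct":
        v = np.linalg.solve(np.eye(x.size) - A, rhs)
    elif method == "series":
        v = rhs.copy()
        term = rhs.copy()
        for _ in range(order):
            term = A @ term
            v += term
        resid = np.linalg.norm((np.eye(x.size) - A) @ v - rhs)
        if resid > residual_tol * max(1.0, np.linalg.norm(rhs)):
            raise RuntimeError(
                f"Neumann series of order {order} not converged "
                f"(residual {resid:.2e}); raise the order or use method='direct'"
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    return np.sign(x) * np.maximum(v, 0.0) ** (1.0 / p.gamma)


class DivisiveNorm(Nonlinearity):
    """Layer wrapper around the canonical divisive normalization.

    When built from a Gaussian kernel spec the tunable parameters are
    (γ, b, σ, c) and H is materialized on demand; otherwise they are
    (γ, b, H) with H flattened row-wise in the packed parameter vector.
    """

    def __init__(self, params: DivNormParams, inverse_method: str = "direct",
                 series_order: int = 10):
        self.params = params
        self.inverse_method = inverse_method
        self.series_order = series_order

    @property
    def d(self) -> int:
        return self.params.b.size

    def forward(self, y: np.ndarray) -> np.ndarray:
        return dn_forward(y, self.params)

    def jacobian(self, y: np.ndarray) -> np.ndarray:
        return dn_jacobian_stimulus(y, self.params)

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return dn_inverse(
            x, self.params, method=self.inverse_method, order=self.series_order
        )

    # -- parameter plumbing --------------------------------------------------
    def param_entries(self) -> list[tuple[str, int, bool]]:
        entries = [("gamma", 1, False), ("b", self.d, False)]
        spec = self.params.kernel_spec
        if spec is not None:
            entries += [("sigma", spec.sigma.size, False), ("c", spec.c.size, False)]
        else:
            entries += [("H", self.d * self.d, True)]
        return entries

    def get_param(self, name: str) -> np.ndarray:
        p = self.params
        if name == "gamma":
            return np.array([p.gamma])
        if name == "b":
            return p.b
        if name == "H" and p.kernel_spec is None:
            return p.H.ravel(order="C")
        if p.kernel_spec is not None and name in ("sigma", "c"):
            return getattr(p.kernel_spec, name)
        raise KeyError(name)

    def set_param(self, name: str, value: np.ndarray) -> None:
        p = self.params
        value = np.asarray(value, dtype=float)
        if name == "gamma":
            p.gamma = float(np.asarray(value).ravel()[0])
        elif name == "b":
            p.b = value.copy()
        elif name == "H" and p.kernel_spec is None:
            p.H = value.reshape(self.d, self.d, order="C")
        elif p.kernel_spec is not None and name in ("sigma", "c"):
            setattr(p.kernel_spec, name, value.copy())
        else:
            raise KeyError(name)

    def jacobian_param(self, y: np.ndarray, name: str) -> np.ndarray:
        if name in ("gamma", "b", "H"):
            return dn_jacobian_params(y, self.params)[name]
        if name in ("sigma", "c"):
            return dn_jacobian_kernel_params(y, self.params)[name]
        raise KeyError(name)
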