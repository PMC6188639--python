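"""Alternative layer nonlinearities: Wilson-Cowan steady state and the
two-gamma tone-mapping curve, plus a plain signed power law.

The Wilson-Cowan population model  ẋ = −αx + μW·f(x) + λy  is used at its
steady state as a nonlinearity.  Its *inverse* is closed form,

    y = (α·x − μW·f(x)) / λ,

so the forward map is computed as a fixed point and its Jacobian as the
matrix inverse of ∇N^{-1} = (1/λ)(αI − μW·D_{f'(x)}).

The two-gamma model is a point-wise saturation  x = sign(y)·|y|^{γ(|y|)}
whose exponent transitions smoothly from γ_L (low inputs) to γ_H (high
inputs) around |y| = μ₁.  A quadratic patch below a small ε makes the curve
and its derivative continuous at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import Nonlinearity

__all__ = [
    "SigmoidSpec",
    "WilsonCowanParams",
    "WilsonCowan",
    "TwoGammaParams",
    "TwoGamma",
    "Power",
    "wc_forward",
    "wc_inverse",
    "wc_jacobian_stimulus",
    "tg_forward",
    "tg_jacobian_stimulus",
    "tg_inverse",
]


# ---------------------------------------------------------------------------
# Wilson-Cowan
# ---------------------------------------------------------------------------

@dataclass
class SigmoidSpec:
    """Named sigmoid with an available derivative; swappable by string."""

    name: str = "tanh"
    slope: float = 1.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self.name == "tanh":
            return np.tanh(self.slope * x)
        raise ValueError(f"unknown sigmoid {self.name!r}")

    def deriv(self, x: np.ndarray) -> np.ndarray:
        if self.name == "tanh":
            return self.slope / np.cosh(self.slope * x) ** 2
        raise ValueError(f"unknown sigmoid {self.name!r}")

    @property
    def sup_deriv(self) -> float:
        if self.name == "tanh":
            return self.slope
        raise ValueError(f"unknown sigmoid {self.name!r}")


@dataclass
class WilsonCowanParams:
    alpha: float
    mu: float
    lam: float
    W: np.ndarray
    f: SigmoidSpec = field(default_factory=SigmoidSpec)
    max_iter: int = 10000
    tol: float = 1e-10
    damping: float = 0.8

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if min(self.alpha, self.lam) <= 0 or self.mu < 0:
            raise ValueError("coupling coefficients must be positive (mu >= 0)")
        # sufficient contraction condition for a unique fixed point
        margin = self.alpha - self.mu * np.max(
            np.sum(np.abs(self.W), axis=1)
        ) * self.f.sup_deriv
        if margin <= 0:
            raise ValueError(
                f"no contraction margin (alpha - mu*||W||_inf*sup|f'| = "
                f"{margin:.3g} <= 0); fixed point may not be unique"
            )


def wc_inverse(x: np.ndarray, p: WilsonCowanParams) -> np.ndarray:
    """Closed-form inverse: y = (α·x − μW·f(x))/λ."""
    x = np.asarray(x, dtype=float)
    return (p.alpha * x - p.mu * (p.W @ p.f(x))) / p.lam


def wc_forward(y: np.ndarray, p: WilsonCowanParams) -> np.ndarray:
    """Steady state x solving 0 = −αx + μW·f(x) + λy (damped iteration)."""
    y = np.asarray(y, dtype=float)
    x = p.lam * y / p.alpha
    kappa = p.damping
    for _ in range(p.max_iter):
        x_new = (1 - kappa) * x + kappa * (p.mu * (p.W @ p.f(x)) + p.lam * y) / p.alpha
        if np.max(np.abs(x_new - x)) < p.tol:
            return x_new
        x = x_new
    # damped iteration stalled: fall back to a multivariate root solver
    sol = optimize.root(
        lambda z: -p.alpha * z + p.mu * (p.W @ p.f(z)) + p.lam * y, x, tol=p.tol
    )
    if not sol.success:
        resid = np.max(np.abs(-p.alpha * sol.x + p.mu * (p.W @ p.f(sol.x)) + p.lam * y))
        raise RuntimeError(
            f"Wilson-Cowan fixed point did not converge (residual {resid:.2e})"
        )
    return sol.x


def wc_jacobian_stimulus(y: np.ndarray, p: WilsonCowanParams,
                         x: np.ndarray | None = None) -> np.ndarray:
    """Forward Jacobian as the matrix inverse of the inverse-map Jacobian
    ∇N^{-1} = (1/λ)(αI − μW·D_{f'(x)}), evaluated at x = N(y)."""
    if x is None:
        x = wc_forward(y, p)
    d = np.asarray(x).size
    Jinv = (p.alpha * np.eye(d) - p.mu * p.W * p.f.deriv(x)[None, :]) / p.lam
    try:
        return np.linalg.inv(Jinv)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "inverse-map Jacobian singular; forward Jacobian undefined"
        ) from exc


class WilsonCowan(Nonlinearity):
    def __init__(self, params: WilsonCowanParams):
        self.params = params

    def forward(self, y: np.ndarray) -> np.ndarray:
        return wc_forward(y, self.params)

    def jacobian(self, y: np.ndarray) -> np.ndarray:
        return wc_jacobian_stimulus(y, self.params)

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return wc_inverse(x, self.params)


# ---------------------------------------------------------------------------
# Two-gamma tone mapping
# ---------------------------------------------------------------------------

@dataclass
class TwoGammaParams:
    """Exponents γ_L/γ_H, transition point μ₁, sharpness m, patch radius ε.

    The quadratic-patch coefficients a1, a2 are derived so that the patched
    curve matches |y|^{γ(|y|)} in value and slope at |y| = ε (C¹ join):

        a1 = (ε·g'(ε) − g(ε)) / ε²,   a2 = (2g(ε) − ε·g'(ε)) / ε

    with g(a) = a^{γ(a)}.
    """

    gamma_l: float
    gamma_h: float
    mu1: float
    m: float
    eps: float = 1e-3
    a1: float = field(init=False)
    a2: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.eps < 1):
            raise ValueError("patch radius eps must be in (0, 1)")
        if self.mu1 <= 0 or self.m <= 0:
            raise ValueError("mu1 and m must be positive")
        g_eps = self._g(self.eps)
        gp_eps = self._g_prime(self.eps)
        self.a1 = (self.eps * gp_eps - g_eps) / self.eps**2
        self.a2 = (2 * g_eps - self.eps * gp_eps) / self.eps
        self._check_monotone()

    def gamma_of(self, a: np.ndarray) -> np.ndarray:
        """Input-dependent exponent γ(|y|) (Naka-Rushton-like transition)."""
        a = np.asarray(a, dtype=float)
        return self.gamma_h - (self.gamma_h - self.gamma_l) * self.mu1**self.m / (
            self.mu1**self.m + a**self.m
        )

    def gamma_prime(self, a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        return (
            (self.gamma_h - self.gamma_l)
            * self.m
            * a ** (self.m - 1)
            * self.mu1**self.m
            / (self.mu1**self.m + a**self.m) ** 2
        )

    def _g(self, a):
        return np.asarray(a, dtype=float) ** self.gamma_of(a)

    def _g_prime(self, a):
        a = np.asarray(a, dtype=float)
        return self._g(a) * (self.gamma_prime(a) * np.log(a) + self.gamma_of(a) / a)

    def _check_monotone(self) -> None:
        grid = np.geomspace(self.eps, 100 * self.mu1, 512)
        if np.any(self._g_prime(grid) <= 0) or (2 * self.a1 * self.eps + self.a2) <= 0:
            raise ValueError(
                "two-gamma curve not monotone for these parameters; "
                "inverse would be ill-defined"
            )


def tg_forward(y: np.ndarray, p: TwoGammaParams) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    a = np.abs(y)
    out = np.empty_like(a)
    lo = a <= p.eps
    out[lo] = p.a1 * a[lo] ** 2 + p.a2 * a[lo]
    out[~lo] = p._g(a[~lo])
    return np.sign(y) * out


def tg_jacobian_stimulus(y: np.ndarray, p: TwoGammaParams) -> np.ndarray:
    """Diagonal Jacobian; the quadratic patch keeps it finite at 0."""
    y = np.asarray(y, dtype=float)
    a = np.abs(y)
    diag = np.empty_like(a)
    lo = a <= p.eps
    diag[lo] = 2 * p.a1 * a[lo] + p.a2
    diag[~lo] = p._g_prime(a[~lo])
    return np.diag(diag)


def tg_inverse(x: np.ndarray, p: TwoGammaParams) -> np.ndarray:
    """Component-wise monotone root of tg_forward(y) = x.

    Quadratic branch solved in closed form; the outer branch by bracketed
    Brent iteration (the curve is monotone by construction).
    """
    x = np.asarray(x, dtype=float)
    ax = np.abs(x)
    out = np.empty_like(ax)
    patch_top = p.a1 * p.eps**2 + p.a2 * p.eps  # = g(eps) by construction
    for k, target in np.ndenumerate(ax):
        if target <= patch_top:
            if abs(p.a1) < 1e-300:
                out[k] = target / p.a2
            else:
                disc = p.a2**2 + 4 * p.a1 * target
                out[k] = (
                    2 * target / (p.a2 + np.sqrt(disc))  # stable smaller-root form
                )
        else:
            hi = max(2 * p.eps, 1.0)
            while p._g(hi) < target:
                hi *= 4.0
            out[k] = optimize.brentq(
                lambda a: p._g(a) - target, p.eps, hi, xtol=1e-14, rtol=1e-15
            )
    return np.sign(x) * out


class TwoGamma(Nonlinearity):
    def __init__(self, params: TwoGammaParams):
        self.params = params

    def forward(self, y: np.ndarray) -> np.ndarray:
        return tg_forward(y, self.params)

    def jacobian(self, y: np.ndarray) -> np.ndarray:
        return tg_jacobian_stimulus(y, self.params)

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return tg_inverse(x, self.params)


# ---------------------------------------------------------------------------
# Signed power law (fixed exponent)
# ---------------------------------------------------------------------------

class Power(Nonlinearity):
    """x = sign(y)·|y|^γ with fixed γ; the brightness curve of the cartoon
    model.  For γ < 1 the Jacobian floors |y| at ``eta`` to stay bounded."""

    def __init__(self, gamma: float, eta: float = 1e-6):
        if gamma <= 0:
            raise ValueError("gamma must be positive")
        self.gamma = gamma
        self.eta = eta

    def forward(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return np.sign(y) * np.abs(y) ** self.gamma

    def jacobian(self, y: np.ndarray) -> np.ndarray:
        ay = np.abs(np.asarray(y, dtype=float))
        if self.gamma < 1:
            ay = np.maximum(ay, self.eta)
        return np.diag(self.gamma * ay ** (self.gamma - 1))

    def inverse(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.sign(x) * np.abs(x) ** (1.0 / self.gamma)
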