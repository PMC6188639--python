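"""Worked example models.

``build_cartoon_model`` is the 3-sensor, 3-pixel, two-layer system used to
interpret every analytic quantity in closed form: layer 1 maps luminance to
brightness through a fixed power law, layer 2 applies frequency analyzers
(DC / low / high rows of an orthonormal F), a band-pass CSF-like gain G, and
a saturating contrast response with no inter-sensor interaction (H = I).
Closed-form expressions for its sensitivity and for the impact of filter
uncertainty are provided to cross-check the generic chain-rule machinery.

``build_reduced_fourlayer`` is a small dimension-preserving analog of a full
retina-to-V1 cascade: brightness → local contrast → CSF-filtered contrast
with spatial masking → orthogonal wavelet with intra-subband Gaussian
masking.  Parameters are package defaults documented in the methods note;
they are chosen so every divisive-normalization stage keeps the spectral
radius of D_|x|·H well below one (the analytic-inverse existence condition)
on the synthetic luminance/contrast fixture grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import fft as sfft

from .core import Cascade, Layer, LinearStage
from .divisive import DivisiveNorm, DivNormParams, GaussianKernelSpec
from .nonlin import Power, TwoGamma, TwoGammaParams, WilsonCowan, WilsonCowanParams

__all__ = [
    "CARTOON_F",
    "CARTOON_G",
    "FourLayerConfig",
    "build_cartoon_model",
    "build_reduced_fourlayer",
    "cartoon_sensitivity_closed_form",
    "cartoon_filter_impact_closed_form",
    "validate_margins",
]

# frequency analyzers of the cartoon model: rows are the DC, low-frequency
# and high-frequency sensors (orthonormal up to the 3-decimal rounding)
CARTOON_F = np.array(
    [
        [0.577, 0.577, 0.577],
        [0.707, 0.000, -0.707],
        [0.408, -0.817, 0.408],
    ]
)
# band-pass frequency-dependent gains (CSF-like)
CARTOON_G = np.diag([0.8, 1.0, 0.2])


def build_cartoon_model(
    gamma1: float = 0.65, b: float | np.ndarray = 5.0, V: np.ndarray | None = None
) -> Cascade:
    """Two-layer 3-pixel model: brightness power law then frequency-analyzer
    contrast response.

    ``V`` is the spectral/luminance integration stage (identity by default:
    the input is already a luminance triplet).  ``b`` is the semisaturation
    of the contrast response, scalar or per-sensor.
    """
    if not 0 < gamma1 <= 1:
        raise ValueError("gamma1 must be in (0, 1]")
    b = np.broadcast_to(np.asarray(b, dtype=float), (3,)).copy()
    L1 = np.eye(3) if V is None else np.asarray(V, dtype=float)
    layer1 = Layer(LinearStage(L1, pinv_ridge=0.0), Power(gamma1))
    dn = DivisiveNorm(DivNormParams(gamma=1.0, b=b, H=np.eye(3)))
    layer2 = Layer(LinearStage(CARTOON_G @ CARTOON_F, pinv_ridge=0.0), dn)
    cascade = Cascade([layer1, layer2])
    # closed-form helpers need the factorization L2 = G·F
    cascade.cartoon = {"gamma1": gamma1, "b": b, "F": CARTOON_F, "G": CARTOON_G}
    return cascade


def cartoon_sensitivity_closed_form(cascade: Cascade, x0: np.ndarray) -> float:
    """det M(x0) of the cartoon model from its closed-form factorization.

    sensitivity = γ₁^{2d} · ∏_k (y¹_k)^{2(γ₁−1)} · det(F)² · ∏_k G_kk²
                  · ∏_k [(1 − |x²_k|)/(b_k + |y²_k|)]²

    (the DC and AC factors of the printed grouping merged into one product;
    det(F)² is kept explicitly — it equals 1 for an exactly orthonormal F).
    """
    info = cascade.cartoon
    states = cascade.forward(np.asarray(x0, dtype=float))
    y1 = np.abs(states[0].y)
    y2, x2 = states[1].y, states[1].x
    d = y1.size
    g1 = info["gamma1"]
    det_j = (
        g1**d
        * np.prod(y1 ** (g1 - 1))
        * np.linalg.det(info["F"])
        * np.prod(np.diag(info["G"]))
        * np.prod((1 - np.abs(x2)) / (info["b"] + np.abs(y2)))
    )
    return float(det_j**2)


def cartoon_filter_impact_closed_form(
    cascade: Cascade, k: int, dF_row: np.ndarray, x0: np.ndarray
) -> float:
    """Closed-form first-order response change of sensor k when row k of the
    frequency analyzer F is perturbed by ΔF_k:

        Δx²_k = [(1 − |x²_k|)/(b_k + |y²_k|)] · G_kk · (ΔF_k · x¹)
    """
    info = cascade.cartoon
    states = cascade.forward(np.asarray(x0, dtype=float))
    x1 = states[0].x
    y2, x2 = states[1].y, states[1].x
    gain = (1 - np.abs(x2[k])) / (info["b"][k] + np.abs(y2[k]))
    return float(gain * info["G"][k, k] * (np.asarray(dF_row) @ x1))


# ---------------------------------------------------------------------------
# reduced four-layer cascade
# ---------------------------------------------------------------------------

@dataclass
class FourLayerConfig:
    size: tuple[int, int] = (16, 16)
    # the reduced field subtends 1 deg at the default size, so the 0.05-deg
    # measurement blur remains a mild perturbation as in a full-scale field
    samples_per_deg: float = 16.0
    variant: str = "dn"  # "dn" or "mixed" (two-gamma brightness + WC wavelet)
    # layer 1: brightness
    gamma1: float = 0.65
    b1: float = 30.0
    # layer 2: local contrast
    mean_sigma_deg: float = 0.125  # width of the local-average window
    mean_weight: float = 0.8  # subtracted fraction of the local mean
    gamma2: float = 1.0
    b2: float = 1.0
    sigma2_deg: float = 0.1
    c2: float = 0.4
    # layer 3: CSF + spatial masking
    csf_peak_cpd: float = 4.0
    csf_floor: float = 0.1
    gamma3: float = 0.65
    b3: float = 2.0
    sigma3_deg: float = 0.08
    c3: float = 0.4
    # layer 4: wavelet + masking
    wavelet: str = "db2"
    levels: int = 2
    gamma4: float = 0.65
    b4: float = 2.0
    sigma4_deg: float = 0.1
    c4: float = 0.4
    # mixed-variant extras
    tg: dict = field(
        default_factory=lambda: dict(gamma_l=0.9, gamma_h=0.6, mu1=0.1, m=2.0)
    )
    wc_mu: float = 0.3


def _grid_positions(h: int, w: int, spd: float) -> np.ndarray:
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return np.column_stack([(ii.ravel() + 0.5) / spd, (jj.ravel() + 0.5) / spd])


def _gaussian_average_matrix(h: int, w: int, sigma_px: float) -> np.ndarray:
    """Row-stochastic circulant local-average operator."""
    from scipy import ndimage

    A = np.empty((h * w, h * w))
    basis = np.zeros((h, w))
    for j in range(h * w):
        basis.ravel()[j] = 1.0
        A[:, j] = ndimage.gaussian_filter(basis, sigma_px, mode="wrap").ravel()
        basis.ravel()[j] = 0.0
    return A


def _dct_csf_matrix(h: int, w: int, spd: float, peak: float, floor: float) -> np.ndarray:
    """Band-pass gain applied in the orthogonal 2-d DCT domain."""
    C1h = sfft.dct(np.eye(h), norm="ortho", axis=0)
    C1w = sfft.dct(np.eye(w), norm="ortho", axis=0)
    C = np.kron(C1h, C1w)  # row-major vec convention
    ki, kj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    f = np.sqrt((ki * spd / (2 * h)) ** 2 + (kj * spd / (2 * w)) ** 2).ravel()
    gain = np.maximum(floor, (f / peak) * np.exp(1 - f / peak))
    return C.T @ (gain[:, None] * C)


def _wavelet_structure(h: int, w: int, wavelet: str, levels: int):
    """Orthogonal 2-d wavelet analysis matrix plus subband metadata.

    Returns (W, subbands) where ``subbands`` is a list of (flat index array,
    (hs, ws)) pairs, one per subband of the coeffs_to_array layout.
    """
    shape = (h, w)
    coeffs = pywt.wavedec2(np.zeros(shape), wavelet, mode="periodization", level=levels)
    _, slices = pywt.coeffs_to_array(coeffs)
    W = np.empty((h * w, h * w))
    basis = np.zeros(shape)
    for j in range(h * w):
        basis.ravel()[j] = 1.0
        arr, _ = pywt.coeffs_to_array(
            pywt.wavedec2(basis, wavelet, mode="periodization", level=levels)
        )
        W[:, j] = arr.ravel()
        basis.ravel()[j] = 0.0
    flat_ids = np.arange(h * w).reshape(shape)
    regions = [slices[0]] + [s[key] for s in slices[1:] for key in ("ad", "da", "dd")]
    subbands = []
    for sl in regions:
        block = flat_ids[tuple(sl)]
        subbands.append((block.ravel(), block.shape))
    return W, subbands


def _kernel_spec_for_grid(
    h: int, w: int, spd: float, sigma_deg: float, c: float
) -> GaussianKernelSpec:
    d = h * w
    return GaussianKernelSpec(
        positions=_grid_positions(h, w, spd),
        subband=np.zeros(d, dtype=int),
        sigma=np.array([sigma_deg]),
        c=np.array([c]),
        dp=1.0 / spd**2,
        structure_sigma=np.ones((d, 1)),
        structure_c=np.ones((d, 1)),
    )


def build_reduced_fourlayer(config: FourLayerConfig | None = None) -> Cascade:
    """Assemble the reduced four-layer cascade (dimension preserving).

    Every linear stage is square and every DN stage keeps its invertibility
    margin by construction: with b of the order of the largest layer energy
    and Gaussian pools c < 0.5, the spectral radius of D_|x|·H stays below
    max|x|·c < 1.
    """
    cfg = config or FourLayerConfig()
    h, w = cfg.size
    d = h * w
    spd = cfg.samples_per_deg

    # layer 1: brightness
    if cfg.variant == "dn":
        L1 = np.eye(d)
        n1 = DivisiveNorm(
            DivNormParams(gamma=cfg.gamma1, b=np.full(d, cfg.b1), H=np.zeros((d, d)))
        )
    elif cfg.variant == "mixed":
        L1 = np.eye(d) / 160.0  # calibrate luminance into [0, 1]
        n1 = TwoGamma(TwoGammaParams(**cfg.tg))
    else:
        raise ValueError(f"unknown variant {cfg.variant!r}")

    # layer 2: deviation from the local mean, normalized by neighbours
    A = _gaussian_average_matrix(h, w, cfg.mean_sigma_deg * spd)
    L2 = np.eye(d) - cfg.mean_weight * A
    spec2 = _kernel_spec_for_grid(h, w, spd, cfg.sigma2_deg, cfg.c2)
    n2 = DivisiveNorm(
        DivNormParams(gamma=cfg.gamma2, b=np.full(d, cfg.b2), kernel_spec=spec2)
    )

    # layer 3: CSF-filtered contrast with spatial masking
    L3 = _dct_csf_matrix(h, w, spd, cfg.csf_peak_cpd, cfg.csf_floor)
    spec3 = _kernel_spec_for_grid(h, w, spd, cfg.sigma3_deg, cfg.c3)
    n3 = DivisiveNorm(
        DivNormParams(gamma=cfg.gamma3, b=np.full(d, cfg.b3), kernel_spec=spec3)
    )

    # layer 4: orthogonal wavelet with intra-subband Gaussian masking
    W, subbands = _wavelet_structure(h, w, cfg.wavelet, cfg.levels)
    n_bands = len(subbands)
    positions = np.empty((d, 2))
    subband = np.empty(d, dtype=int)
    struct = np.zeros((d, n_bands))
    blocks: list[tuple[np.ndarray, tuple[int, int]]] = []
    for band, (ids, (hs, ws)) in enumerate(subbands):
        # each subband samples the full field at its own (coarser) density
        positions[ids] = _grid_positions(hs, ws, spd * hs / h)
        subband[ids] = band
        struct[ids, band] = 1.0
        blocks.append((ids, (hs, ws)))
    spec4 = GaussianKernelSpec(
        positions=positions,
        subband=subband,
        sigma=np.full(n_bands, cfg.sigma4_deg),
        c=np.full(n_bands, cfg.c4),
        dp=1.0 / spd**2,
        structure_sigma=struct,
        structure_c=struct,
    )
    if cfg.variant == "mixed":
        from .divisive import build_gaussian_H

        Wk = build_gaussian_H(spec4)
        row = Wk.sum(axis=1, keepdims=True)
        Wk = Wk / np.maximum(row, 1e-12)  # row-stochastic decaying kernel
        n4 = WilsonCowan(
            WilsonCowanParams(alpha=1.0, mu=cfg.wc_mu, lam=1.0, W=Wk)
        )
    else:
        n4 = DivisiveNorm(
            DivNormParams(gamma=cfg.gamma4, b=np.full(d, cfg.b4), kernel_spec=spec4)
        )

    # all four stages are square and well conditioned by construction, so
    # they are inverted exactly (no pseudoinverse ridge needed)
    cascade = Cascade(
        [
            Layer(LinearStage(L1, pinv_ridge=0.0), n1),
            Layer(LinearStage(L2, pinv_ridge=0.0), n2),
            Layer(LinearStage(L3, pinv_ridge=0.0), n3),
            Layer(LinearStage(W, pinv_ridge=0.0), n4),
        ]
    )
    cascade.response_blocks = blocks
    cascade.samples_per_deg = spd
    cascade.config = cfg
    return cascade


def validate_margins(cascade: Cascade, images: np.ndarray) -> float:
    """Max spectral radius of D_|x|·H over all DN layers and all images.

    Raises when any layer violates the invertibility bound (radius >= 1).
    """
    from .divisive import dn_invertibility_margin

    images = np.atleast_2d(np.asarray(images, dtype=float))
    worst = 0.0
    for x0 in images:
        states = cascade.forward(x0)
        for i, lay in enumerate(cascade.layers):
            if isinstance(lay.nonlin, DivisiveNorm):
                radius = dn_invertibility_margin(states[i].x, lay.nonlin.params)
                worst = max(worst, radius)
                if radius >= 1:
                    raise ValueError(
                        f"invertibility violated at layer {i + 1}: "
                        f"spectral radius {radius:.3f} >= 1"
                    )
    return worst
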