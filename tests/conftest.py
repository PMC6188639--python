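import numpy as np
import pytest

from lnlcascade.core import Cascade, Layer, LinearStage
from lnlcascade.divisive import DivisiveNorm, DivNormParams, GaussianKernelSpec
from lnlcascade.toys import build_cartoon_model, build_reduced_fourlayer


def random_dn_params(rng: np.random.Generator, d: int,
                     gamma_range=(0.5, 1.5)) -> DivNormParams:
    """A random valid DN parameter bundle with a comfortable invertibility
    margin (row pools of H well below 1)."""
    H = rng.uniform(0.0, 0.3 / d, (d, d)) + np.diag(rng.uniform(0.05, 0.2, d))
    return DivNormParams(
        gamma=float(rng.uniform(*gamma_range)),
        b=rng.uniform(0.5, 2.0, d),
        H=H,
    )


def random_signed(rng: np.random.Generator, d: int, lo=0.2, hi=2.0) -> np.ndarray:
    """Random vector bounded away from zero (where γ<1 derivatives blow up)."""
    return rng.uniform(lo, hi, d) * rng.choice([-1.0, 1.0], d)


def grid_kernel_spec(rng: np.random.Generator, side: int = 3,
                     shared: bool = False) -> GaussianKernelSpec:
    d = side * side
    pos = np.array([[i, j] for i in range(side) for j in range(side)], float) * 0.1
    if shared:
        return GaussianKernelSpec(
            positions=pos, subband=np.zeros(d, int),
            sigma=np.array([rng.uniform(0.1, 0.25)]),
            c=np.array([rng.uniform(0.2, 0.45)]), dp=0.01,
            structure_sigma=np.ones((d, 1)), structure_c=np.ones((d, 1)),
        )
    return GaussianKernelSpec(
        positions=pos, subband=np.zeros(d, int),
        sigma=rng.uniform(0.1, 0.25, d), c=rng.uniform(0.2, 0.45, d), dp=0.01,
    )


def small_dn_cascade(rng: np.random.Generator, dims=(4, 4, 4)) -> Cascade:
    """Random small multi-layer DN cascade for chain-rule checks."""
    layers = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        L = rng.uniform(-0.8, 0.8, (d_out, d_in)) + np.eye(d_out, d_in)
        layers.append(Layer(LinearStage(L), DivisiveNorm(random_dn_params(rng, d_out))))
    return Cascade(layers)


@pytest.fixture(scope="session")
def cartoon():
    return build_cartoon_model(gamma1=0.65, b=5.0)


@pytest.fixture(scope="session")
def fourlayer():
    return build_reduced_fourlayer()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
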