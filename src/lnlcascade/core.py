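"""Data model for stimuli, L+NL layers and cascades.

A visual stimulus is a raster image flattened to a column vector; a model is an
ordered cascade of layers, each a linear filter bank ``L`` followed by a
(possibly interacting) saturating nonlinearity ``N``.  The cascade response is

    x^i = N^(i)(L^i · x^{i-1}),   i = 1..n

and the full parameter set can be packed into a single flat vector with a
layout map, which is what the parameter-Jacobian machinery and the optimizers
consume.

Conventions fixed here and relied on everywhere else:

* Vectorization is last-dimension-first (colour/band index fastest), i.e. a
  C-order ravel of an ``(h, w, bands)`` array.  Matrices built elsewhere
  (frequency analyzers, wavelets, interaction kernels) assume this scan order.
* All signals are column vectors; Jacobians are rows-of-outputs by
  columns-of-inputs.
* ``sign(0) = 0`` (numpy's convention), so every odd nonlinearity maps 0 to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Stimulus",
    "LayerState",
    "Nonlinearity",
    "Identity",
    "LinearStage",
    "Layer",
    "Cascade",
    "ParamEntry",
    "ParameterLayout",
    "vectorize",
    "devectorize",
    "pack_params",
    "unpack_params",
]

SCAN_ORDER = "last-dimension-first"


@dataclass
class Stimulus:
    """A vectorized image with shape metadata.

    ``values`` holds luminance (or radiance) in cd/m² after calibration; the
    original raster is recovered exactly by :func:`devectorize`.
    """

    values: np.ndarray
    shape: tuple[int, int, int]
    vectorization: str = SCAN_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        h, w, b = self.shape
        if self.values.size != h * w * b:
            raise ValueError(
                f"stimulus length {self.values.size} != {h}x{w}x{b}"
            )

    @property
    def d(self) -> int:
        return self.values.size

    def image(self) -> np.ndarray:
        return devectorize(self)


def vectorize(image: np.ndarray) -> Stimulus:
    """Flatten a raster image to a column-vector stimulus.

    Accepts 2-d ``(h, w)`` or 3-d ``(h, w, bands)`` arrays.  The scan order is
    last-dimension-first (bands fastest), which a C-order ravel implements.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("non-finite values in input image")
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3:
        raise ValueError("expected a 2-d or 3-d array")
    return Stimulus(values=image.ravel(order="C"), shape=image.shape)


def devectorize(stim: Stimulus) -> np.ndarray:
    return stim.values.reshape(stim.shape, order="C")


@dataclass
class LayerState:
    """Intermediate signals of one layer: linear output y and response x."""

    y: np.ndarray
    x: np.ndarray


class Nonlinearity:
    """Interface every layer nonlinearity implements.

    Subclasses provide the forward map, its Jacobian with respect to the
    input, the analytic (or iterative) inverse, and - when the nonlinearity
    has tunable parameters - named parameter vectors together with the
    corresponding parameter Jacobians.
    """

    def forward(self, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def jacobian(self, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def inverse(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # -- parameter plumbing (empty by default) -------------------------------
    def param_entries(self) -> list[tuple[str, int, bool]]:
        """(name, length, row-wise-matrix flag) for each tunable parameter."""
        return []

    def get_param(self, name: str) -> np.ndarray:
        raise KeyError(name)

    def set_param(self, name: str, value: np.ndarray) -> None:
        raise KeyError(name)

    def jacobian_param(self, y: np.ndarray, name: str) -> np.ndarray:
        raise KeyError(name)


class Identity(Nonlinearity):
    """x = y; the degenerate nonlinearity used for purely linear layers."""

    def forward(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float).copy()

    def jacobian(self, y: np.ndarray) -> np.ndarray:
        return np.eye(len(y))

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float).copy()


@dataclass
class LinearStage:
    """A linear filter bank, one receptive field per row.

    ``pinv_ridge`` scales the Tikhonov term used when the stage is undone
    during decoding: the effective regularizer is ``pinv_ridge * s_max**2``
    with ``s_max`` the largest singular value.
    """

    L: np.ndarray
    pinv_ridge: float = 1e-8

    def __post_init__(self) -> None:
        self.L = np.atleast_2d(np.asarray(self.L, dtype=float))
        if not np.all(np.isfinite(self.L)):
            raise ValueError("non-finite entries in linear stage")
        if self.pinv_ridge < 0:
            raise ValueError("pinv_ridge must be nonnegative")
        self._svd: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @property
    def d_out(self) -> int:
        return self.L.shape[0]

    @property
    def d_in(self) -> int:
        return self.L.shape[1]

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.d_in:
            raise ValueError(f"expected input of length {self.d_in}, got {x.shape}")
        return x @ self.L.T if x.ndim > 1 else self.L @ x

    def condition_number(self) -> float:
        s = self._svd_cached()[1]
        smin = s[-1]
        return np.inf if smin == 0 else s[0] / smin

    def _svd_cached(self):
        if self._svd is None:
            self._svd = np.linalg.svd(self.L, full_matrices=False)
        return self._svd

    def pinv_apply(self, y: np.ndarray) -> np.ndarray:
        """Ridge-regularized pseudoinverse applied to a response vector."""
        U, s, Vt = self._svd_cached()
        ridge = self.pinv_ridge * s[0] ** 2 if s[0] > 0 else 0.0
        filt = s / (s**2 + ridge)
        return Vt.T @ (filt * (U.T @ np.asarray(y, dtype=float)))


@dataclass
class Layer:
    linear: LinearStage
    nonlin: Nonlinearity

    def forward(self, x_prev: np.ndarray) -> LayerState:
        y = self.linear.apply(x_prev)
        return LayerState(y=y, x=self.nonlin.forward(y))


class Cascade:
    """An ordered feed-forward composition of L+NL layers."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)
        for a, b in zip(self.layers, self.layers[1:]):
            if a.linear.d_out != b.linear.d_in:
                raise ValueError(
                    f"incompatible layer dims: {a.linear.d_out} -> {b.linear.d_in}"
                )
        # optional metadata used by decoding (per-subband blur) and patch-wise
        # geometry: list of (slice, (h, w)) blocks tiling the response vector
        self.response_blocks: list[tuple[slice, tuple[int, int]]] | None = None
        self.samples_per_deg: float | None = None

    @property
    def n(self) -> int:
        return len(self.layers)

    @property
    def dims(self) -> tuple[int, ...]:
        return (self.layers[0].linear.d_in,) + tuple(
            lay.linear.d_out for lay in self.layers
        )

    def forward(self, x0: np.ndarray | Stimulus) -> list[LayerState]:
        """Run the cascade, returning every intermediate (y^i, x^i)."""
        x = x0.values if isinstance(x0, Stimulus) else np.asarray(x0, dtype=float)
        states: list[LayerState] = []
        for i, lay in enumerate(self.layers):
            try:
                state = lay.forward(x)
            except Exception as exc:  # attach the offending layer index
                raise RuntimeError(f"forward failed at layer {i + 1}: {exc}") from exc
            states.append(state)
            x = state.x
        return states

    def response(self, x0: np.ndarray | Stimulus) -> np.ndarray:
        return self.forward(x0)[-1].x


@dataclass
class ParamEntry:
    layer: int  # 0-based layer index
    name: str  # "L" or a nonlinearity parameter name
    offset: int
    length: int
    rowwise: bool  # matrices are flattened row-wise (vect of the transpose)


@dataclass
class ParameterLayout:
    entries: list[ParamEntry] = field(default_factory=list)

    @property
    def size(self) -> int:
        return sum(e.length for e in self.entries)


TrainableSpec = dict[int, list[str]]


def _layer_params(layer: Layer) -> list[tuple[str, int, bool]]:
    d_out, d_in = layer.linear.L.shape
    return [("L", d_out * d_in, True)] + list(layer.nonlin.param_entries())


def pack_params(
    cascade: Cascade, trainable: TrainableSpec | None = None
) -> tuple[np.ndarray, ParameterLayout]:
    """Concatenate the cascade's parameters into a flat vector Θ.

    ``trainable`` restricts the layout to ``{layer_index: [names]}``; by
    default every linear stage and every nonlinearity parameter is included.
    Matrix-valued parameters are flattened row-wise.
    """
    layout = ParameterLayout()
    pieces: list[np.ndarray] = []
    offset = 0
    for i, lay in enumerate(cascade.layers):
        available = {name: (size, rw) for name, size, rw in _layer_params(lay)}
        names = trainable.get(i, []) if trainable is not None else list(available)
        for name in names:
            if name not in available:
                raise KeyError(f"layer {i} has no parameter {name!r}")
            size, rowwise = available[name]
            if name == "L":
                vec = lay.linear.L.ravel(order="C")  # row-wise vect(L^T)
            else:
                vec = np.asarray(lay.nonlin.get_param(name), dtype=float).ravel()
            if vec.size != size:
                raise ValueError(f"parameter {name!r} has length {vec.size} != {size}")
            layout.entries.append(ParamEntry(i, name, offset, size, rowwise))
            pieces.append(vec)
            offset += size
    theta = np.concatenate(pieces) if pieces else np.empty(0)
    return theta, layout


def unpack_params(theta: np.ndarray, layout: ParameterLayout, cascade: Cascade) -> None:
    """Write a flat parameter vector back into the cascade (in place)."""
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.size != layout.size:
        raise ValueError(f"theta length {theta.size} != layout size {layout.size}")
    for e in layout.entries:
        piece = theta[e.offset : e.offset + e.length]
        lay = cascade.layers[e.layer]
        if e.name == "L":
            lay.linear.L = piece.reshape(lay.linear.L.shape, order="C")
            lay.linear._svd = None
        else:
            lay.nonlin.set_param(e.name, piece)
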