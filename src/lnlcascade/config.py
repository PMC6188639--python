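"""Model configuration files.

A cascade is described by a JSON/YAML document with one block per layer:

    layers:
      - type: linear+dn          # or linear+wc | linear+tg | linear+identity
        L: [[...], ...]          # inline matrix, or {csv: path}
        gamma: 0.65
        b: [...]
        H: [[...], ...]          # or a Gaussian kernel spec under `kernel`
      - ...

Matrices may be inline nested lists or ``{csv: relative/path.csv}``; kernel
specs serialize their positions/subband/σ/c/structure fields.  ``to_config``
and ``from_config`` round-trip every layer type the package defines.
"""

from __future__ import annotations

import json
import os

import numpy as np
import yaml

from .core import Cascade, Identity, Layer, LinearStage
from .divisive import DivisiveNorm, DivNormParams, GaussianKernelSpec
from .nonlin import (
    Power,
    SigmoidSpec,
    TwoGamma,
    TwoGammaParams,
    WilsonCowan,
    WilsonCowanParams,
)

__all__ = ["to_config", "from_config", "save_model", "load_model"]


def _encode_matrix(M: np.ndarray):
    return np.asarray(M).tolist()


def _decode_matrix(entry, base_dir: str) -> np.ndarray:
    if isinstance(entry, dict) and "csv" in entry:
        return np.loadtxt(os.path.join(base_dir, entry["csv"]), delimiter=",")
    return np.asarray(entry, dtype=float)


def _encode_kernel(spec: GaussianKernelSpec) -> dict:
    out = {
        "positions": _encode_matrix(spec.positions),
        "subband": spec.subband.tolist(),
        "sigma": spec.sigma.tolist(),
        "c": spec.c.tolist(),
        "dp": float(spec.dp),
    }
    if spec.structure_sigma is not None:
        out["structure_sigma"] = _encode_matrix(spec.structure_sigma)
    if spec.structure_c is not None:
        out["structure_c"] = _encode_matrix(spec.structure_c)
    return out


def _decode_kernel(d: dict, base_dir: str) -> GaussianKernelSpec:
    return GaussianKernelSpec(
        positions=_decode_matrix(d["positions"], base_dir),
        subband=np.asarray(d["subband"], dtype=int),
        sigma=np.asarray(d["sigma"], dtype=float),
        c=np.asarray(d["c"], dtype=float),
        dp=float(d["dp"]),
        structure_sigma=(
            _decode_matrix(d["structure_sigma"], base_dir)
            if "structure_sigma" in d
            else None
        ),
        structure_c=(
            _decode_matrix(d["structure_c"], base_dir) if "structure_c" in d else None
        ),
    )


def to_config(cascade: Cascade) -> dict:
    layers = []
    for lay in cascade.layers:
        block: dict = {"L": _encode_matrix(lay.linear.L),
                       "pinv_ridge": lay.linear.pinv_ridge}
        nl = lay.nonlin
        if isinstance(nl, DivisiveNorm):
            p = nl.params
            block["type"] = "linear+dn"
            block["gamma"] = float(p.gamma)
            block["b"] = p.b.tolist()
            if p.kernel_spec is not None:
                block["kernel"] = _encode_kernel(p.kernel_spec)
            else:
                block["H"] = _encode_matrix(p.H)
        elif isinstance(nl, WilsonCowan):
            p = nl.params
            block["type"] = "linear+wc"
            block.update(
                alpha=p.alpha, mu=p.mu, lam=p.lam, W=_encode_matrix(p.W),
                sigmoid=p.f.name, slope=p.f.slope,
            )
        elif isinstance(nl, TwoGamma):
            p = nl.params
            block["type"] = "linear+tg"
            block.update(
                gamma_l=p.gamma_l, gamma_h=p.gamma_h, mu1=p.mu1, m=p.m, eps=p.eps
            )
        elif isinstance(nl, Power):
            block["type"] = "linear+power"
            block["gamma"] = nl.gamma
        elif isinstance(nl, Identity):
            block["type"] = "linear+identity"
        else:
            raise TypeError(f"cannot serialize nonlinearity {type(nl).__name__}")
        layers.append(block)
    out = {"layers": layers}
    if cascade.samples_per_deg is not None:
        out["samples_per_deg"] = cascade.samples_per_deg
    return out


def from_config(doc: dict, base_dir: str = ".") -> Cascade:
    layers = []
    for block in doc["layers"]:
        stage = LinearStage(
            _decode_matrix(block["L"], base_dir),
            pinv_ridge=float(block.get("pinv_ridge", 1e-8)),
        )
        kind = block.get("type", "linear+identity")
        if kind == "linear+dn":
            params = DivNormParams(
                gamma=float(block["gamma"]),
                b=np.asarray(block["b"], dtype=float),
                H=_decode_matrix(block["H"], base_dir) if "H" in block else None,
                kernel_spec=(
                    _decode_kernel(block["kernel"], base_dir)
                    if "kernel" in block
                    else None
                ),
            )
            nl = DivisiveNorm(params)
        elif kind == "linear+wc":
            nl = WilsonCowan(
                WilsonCowanParams(
                    alpha=float(block["alpha"]),
                    mu=float(block["mu"]),
                    lam=float(block["lam"]),
                    W=_decode_matrix(block["W"], base_dir),
                    f=SigmoidSpec(block.get("sigmoid", "tanh"),
                                  float(block.get("slope", 1.0))),
                )
            )
        elif kind == "linear+tg":
            nl = TwoGamma(
                TwoGammaParams(
                    gamma_l=float(block["gamma_l"]),
                    gamma_h=float(block["gamma_h"]),
                    mu1=float(block["mu1"]),
                    m=float(block["m"]),
                    eps=float(block.get("eps", 1e-3)),
                )
            )
        elif kind == "linear+power":
            nl = Power(float(block["gamma"]))
        elif kind == "linear+identity":
            nl = Identity()
        else:
            raise ValueError(f"unknown layer type {kind!r}")
        layers.append(Layer(stage, nl))
    cascade = Cascade(layers)
    if "samples_per_deg" in doc:
        cascade.samples_per_deg = float(doc["samples_per_deg"])
    return cascade


def save_model(cascade: Cascade, path: str) -> None:
    doc = to_config(cascade)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(doc, fh)
        else:
            yaml.safe_dump(doc, fh)


def load_model(path: str) -> Cascade:
    with open(path) as fh:
        doc = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return from_config(doc, base_dir=os.path.dirname(path) or ".")
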