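"""Marker-wise variance-stabilizing transforms.

Three transforms cover the major cytometry modalities:

* **autologicle** — the logicle (biexponential) display transform with the
  linearization width ``W`` estimated per marker from the negative events;
  the standard choice for fluorescence data.
* **arcsinh** — ``asinh(x / cofactor)`` with cofactor 5, the mass-cytometry
  convention.
* **CLR** — centered log-ratio for antibody-capture (ADT) count data.

All transforms are strictly monotone per marker, so rank order of raw
intensities is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import CytoTable

__all__ = [
    "LogicleParams",
    "ArcsinhParams",
    "ClrParams",
    "Logicle",
    "estimate_logicle_w",
    "autologicle",
    "arcsinh_transform",
    "clr_transform",
]


@dataclass
class LogicleParams:
    """Logicle scale parameters.

    T is the top of scale, M the number of display decades, W the
    linearization width in decades (0 gives a plain log scale), A additional
    negative display decades, and r the negative-data quantile used by the
    automatic W estimate.
    """

    T: float = 262144.0
    M: float = 4.5
    W: float = 0.5
    A: float = 0.0
    r: float = 0.05

    def validate(self) -> None:
        if self.T <= 0 or self.M <= 0 or self.A < 0:
            raise ValueError("require T > 0, M > 0, A >= 0")
        if not 0 <= self.W <= self.M / 2:
            raise ValueError("require 0 <= W <= M/2")


@dataclass
class ArcsinhParams:
    cofactor: float = 5.0

    def validate(self) -> None:
        if self.cofactor <= 0:
            raise ValueError("cofactor must be > 0")


@dataclass
class ClrParams:
    pseudocount: float = 1.0
    axis: str = "per_cell"  # or "per_marker"

    def validate(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.axis not in ("per_cell", "per_marker"):
            raise ValueError("axis must be 'per_cell' or 'per_marker'")


class Logicle:
    """The biexponential scale function and its inverse.

    The display coordinate ``y`` is normalized to [0, 1] over the full
    ``M + A`` decades, so the top-of-scale data value ``T`` maps to exactly 1.
    ``biexponential(y)`` maps display to data; the logicle transform is its
    inverse, evaluated by vectorized bisection (strictly monotone, solved to
    |tol| < 1e-8 in y).
    """

    def __init__(self, params: LogicleParams):
        params.validate()
        T, M, W, A = params.T, params.M, params.W, params.A
        self.params = params
        span = M + A
        b = span * np.log(10.0)
        w = W / span
        x2 = A / span
        x1 = x2 + w
        x0 = x2 + 2.0 * w
        if w == 0:
            d = b
        else:
            # d solves 2 (ln d - ln b) + w (d + b) = 0 on (0, b]
            d = brentq(
                lambda dd: 2.0 * (np.log(dd) - np.log(b)) + w * (dd + b),
                b * 1e-12,
                b,
                xtol=1e-14,
            )
        c_a = np.exp(x0 * (b + d))
        mf_a = np.exp(b * x1) - c_a / np.exp(d * x1)
        a = T / (np.exp(b) - mf_a - c_a / np.exp(d))
        self._a, self._b, self._c, self._d, self._f = a, b, c_a * a, d, -mf_a * a

    def biexponential(self, y: np.ndarray | float) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return self._a * np.exp(self._b * y) - self._c * np.exp(-self._d * y) + self._f

    def transform(self, x: np.ndarray | float, tol: float = 1e-8) -> np.ndarray:
        """Inverse biexponential by monotone bisection."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values cannot be logicle-transformed")
        lo = np.full(x.shape, -1.0)
        hi = np.full(x.shape, 2.0)
        # widen until the bracket contains every value
        while np.any(self.biexponential(lo) > x):
            lo = np.where(self.biexponential(lo) > x, lo * 2.0, lo)
        while np.any(self.biexponential(hi) < x):
            hi = np.where(self.biexponential(hi) < x, hi * 2.0, hi)
        # 80 halvings take the bracket to float64 resolution, far inside tol,
        # so the forward/inverse round-trip is exact to ~1e-9 in data units
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            below = self.biexponential(mid) < x
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
            if np.max(hi - lo) < 1e-16:
                break
        return 0.5 * (lo + hi)


def estimate_logicle_w(
    values: np.ndarray,
    T: float = 262144.0,
    M: float = 4.5,
    neg_quantile: float = 0.05,
    min_neg: int = 10,
    fallback_w: float = 0.5,
) -> float:
    """Estimate the linearization width W from a marker's negative events.

    ``r`` is the ``neg_quantile`` quantile of the negative values and
    ``W = max(0, (M - log10(T / |r|)) / 2)``; markers with fewer than
    ``min_neg`` negative events fall back to ``W = fallback_w``.  Estimates
    above M/2 are clamped (with a warning).
    """
    neg = values[values < 0]
    if neg.size < min_neg:
        return fallback_w
    r = float(np.quantile(neg, neg_quantile))
    W = max(0.0, (M - np.log10(T / abs(r))) / 2.0)
    if W > M / 2:
        warnings.warn(
            f"estimated W={W:.3f} exceeds M/2={M / 2:.3f}; clamping", stacklevel=2
        )
        W = M / 2
    return W


def autologicle(
    table: CytoTable,
    markers: list[str] | None = None,
    params_override: LogicleParams | None = None,
) -> CytoTable:
    """Logicle-transform ``expr_raw`` marker-wise with automatic W estimation.

    W is estimated per marker from the pooled negative events of all samples
    (a per-file estimate is not provided; parameters are pooled so intensities
    stay comparable across files).  Estimated parameters are recorded in the
    provenance log.
    """
    markers = markers or table.markers
    base = params_override or LogicleParams()
    raw = table.expr_raw[markers].to_numpy()
    if not np.all(np.isfinite(raw)):
        raise ValueError("expr_raw contains non-finite values")

    out = table.copy()
    if out.expr is None:
        out.expr = table.expr_raw.astype(float).copy()
    fitted: dict[str, dict] = {}
    for m in markers:
        col = table.expr_raw[m].to_numpy(dtype=float)
        W = (
            base.W
            if params_override is not None
            else estimate_logicle_w(col, T=base.T, M=base.M, neg_quantile=base.r)
        )
        p = LogicleParams(T=base.T, M=base.M, W=W, A=base.A, r=base.r)
        out.expr[m] = Logicle(p).transform(col)
        fitted[m] = {"T": p.T, "M": p.M, "W": W, "A": p.A}
    out.log_event("autologicle", markers=markers, params=fitted)
    return out


def arcsinh_transform(
    table: CytoTable,
    markers: list[str] | None = None,
    params: ArcsinhParams | None = None,
) -> CytoTable:
    """``expr = asinh(expr_raw / cofactor)`` with the field-standard cofactor 5."""
    params = params or ArcsinhParams()
    params.validate()
    markers = markers or table.markers
    out = table.copy()
    if out.expr is None:
        out.expr = table.expr_raw.astype(float).copy()
    out.expr[markers] = np.arcsinh(
        table.expr_raw[markers].to_numpy(dtype=float) / params.cofactor
    )
    out.log_event("arcsinh_transform", cofactor=params.cofactor, markers=markers)
    return out


def clr_transform(
    table: CytoTable,
    markers: list[str] | None = None,
    params: ClrParams | None = None,
) -> CytoTable:
    """Centered log-ratio transform for antibody-capture count data.

    Per cell (default axis): ``y_i = ln((x_i + pc) / geometric_mean_j(x_j + pc))``,
    so each cell's transformed values sum to zero.
    """
    params = params or ClrParams()
    params.validate()
    markers = markers or table.markers
    x = table.expr_raw[markers].to_numpy(dtype=float)
    if params.pseudocount == 0 and np.any(x == 0):
        raise ValueError("zero counts require a positive pseudocount")
    logx = np.log(x + params.pseudocount)
    axis = 1 if params.axis == "per_cell" else 0
    y = logx - logx.mean(axis=axis, keepdims=True)
    out = table.copy()
    if out.expr is None:
        out.expr = table.expr_raw.astype(float).copy()
    out.expr[markers] = y
    out.log_event(
        "clr_transform", pseudocount=params.pseudocount, axis=params.axis,
        markers=markers,
    )
    return out
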