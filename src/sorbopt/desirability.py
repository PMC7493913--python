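"""Desirability scoring and deterministic optimum location on the cube.

A maximize-goal desirability maps a response ``y`` onto [0, 1]:

    d = 0                      for y < L
    d = ((y - L)/(U - L))^w    for L <= y <= U
    d = 1                      for y > U

and the composite desirability of several responses is their geometric
mean.  For a single maximized response, maximizing D is equivalent to
maximizing the predicted response itself (d is non-decreasing in y), so
the optimizer scans a dense coded grid and polishes the best cell with a
bounded quasi-Newton step on the predicted response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .design import FactorSpec
from .errors import ValidationError
from .rsm import QuadraticModel, predict

__all__ = [
    "DesirabilitySpec",
    "OptimumReport",
    "d_single",
    "d_composite",
    "maximize_desirability",
]


@dataclass(frozen=True)
class DesirabilitySpec:
    """Maximize-goal desirability bounds: L (unacceptable), U (ideal), weight."""

    lower: float
    upper: float
    weight: float = 1.0
    goal: str = "maximize"

    def __post_init__(self) -> None:
        if self.goal != "maximize":
            raise ValidationError(f"only the 'maximize' goal is supported, got {self.goal!r}")
        if not self.lower < self.upper:
            raise ValidationError(f"need lower < upper, got ({self.lower}, {self.upper})")
        if not self.weight > 0:
            raise ValidationError(f"weight must be > 0, got {self.weight}")


def d_single(y: float, spec: DesirabilitySpec) -> float:
    """Desirability of one response value under a maximize goal."""
    if y < spec.lower:
        return 0.0
    if y > spec.upper:
        return 1.0
    return float(((y - spec.lower) / (spec.upper - spec.lower)) ** spec.weight)


def d_composite(ds: Sequence[float]) -> float:
    """Geometric mean of individual desirabilities; 0 if any is 0."""
    arr = np.asarray(list(ds), dtype=float)
    if arr.size == 0:
        raise ValidationError("composite desirability of an empty list is undefined")
    if np.any((arr < 0) | (arr > 1)):
        raise ValidationError("desirabilities must lie in [0, 1]")
    if np.any(arr == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(arr))))


@dataclass
class OptimumReport:
    """Located optimum: coded/actual setting, prediction and desirability."""

    coded: np.ndarray
    actual: np.ndarray | None
    predicted: float
    desirability: float
    composite: float

    def to_kv(self, factor_names: Sequence[str] | None = None) -> dict[str, float]:
        names = (
            list(factor_names)
            if factor_names is not None
            else [f"x{i+1}" for i in range(len(self.coded))]
        )
        out = {f"coded_{n}": float(v) for n, v in zip(names, self.coded)}
        if self.actual is not None:
            out.update({f"actual_{n}": float(v) for n, v in zip(names, self.actual)})
        out["predicted_response"] = self.predicted
        out["desirability"] = self.desirability
        out["composite_desirability"] = self.composite
        return out


def _grid_axes(bounds: np.ndarray, step: float) -> list[np.ndarray]:
    axes = []
    for lo, hi in bounds:
        n = int(round((hi - lo) / step))
        axes.append(np.linspace(lo, hi, n + 1))
    return axes


def maximize_desirability(
    model: QuadraticModel,
    spec: DesirabilitySpec,
    bounds: np.ndarray | None = None,
    factors: Sequence[FactorSpec] | None = None,
    grid_step: float = 0.01,
) -> OptimumReport:
    """Deterministic maximizer of (composite) desirability over the cube.

    Dense grid scan at ``grid_step`` (first-encountered maximum in
    row-major order wins ties) followed by an L-BFGS-B polish from the
    best cell.  Because d is monotone in y for a maximize goal, the
    polish runs on the predicted response; the two routes agree by
    construction.  ``factors``, when given, decode the optimum into
    actual units.
    """
    k = len(model.factor_names)
    if bounds is None:
        bounds = np.array([[-1.0, 1.0]] * k)
    bounds = np.asarray(bounds, dtype=float).reshape(k, 2)
    axes = _grid_axes(bounds, grid_step)

    # chunk the scan along the first axis to bound memory
    best_val, best_pt = -np.inf, None
    tail = np.meshgrid(*axes[1:], indexing="ij") if k > 1 else []
    tail_flat = [t.ravel() for t in tail]
    n_tail = tail_flat[0].size if tail_flat else 1
    for x0 in axes[0]:
        pts = np.empty((n_tail, k))
        pts[:, 0] = x0
        for j, col in enumerate(tail_flat, start=1):
            pts[:, j] = col
        vals = np.atleast_1d(predict(model, pts))
        i = int(np.argmax(vals))  # first occurrence on ties
        if vals[i] > best_val:
            best_val, best_pt = float(vals[i]), pts[i].copy()

    res = optimize.minimize(
        lambda p: -predict(model, p),
        x0=best_pt,
        method="L-BFGS-B",
        bounds=[tuple(b) for b in bounds],
    )
    opt = np.clip(res.x, bounds[:, 0], bounds[:, 1])
    if -res.fun < best_val:  # polish must never lose to its own start
        opt = best_pt
    y_opt = float(predict(model, opt))
    d = d_single(y_opt, spec)
    actual = None
    if factors is not None:
        actual = np.array([f.to_actual(c) for f, c in zip(factors, opt)])
    return OptimumReport(
        coded=np.asarray(opt, dtype=float),
        actual=actual,
        predicted=y_opt,
        desirability=d,
        composite=d_composite([d]),
    )
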