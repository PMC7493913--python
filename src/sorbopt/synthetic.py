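"""Synthetic data with the statistical structure the analysis assumes.

Two generators and one small ranking utility:

* Box-Behnken response tables — a known quadratic surface evaluated at
  the coded design points plus independent homoscedastic Gaussian noise.
  Centre replicates receive independent draws, which is exactly what
  creates pure error in the ANOVA.
* Kinetic traces — the closed forms of the two rate laws,

      first order   q_t = q_e (1 - exp(-k1 t))
      second order  q_t = q_e^2 k2 t / (1 + q_e k2 t),

  converted to residual concentrations via the mass balance
  C_t = C_0 - m q_t / V, with Gaussian noise added on C_t.
* Electronegativity ranking of metal ions — heavier-binding cations tend
  to be the more electronegative ones, so a descending sort predicts the
  qualitative multi-metal removal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import DesignTable, FactorSpec, build_bbd
from .errors import ValidationError
from .kinetics import KineticTrace
from .rsm import QuadraticModel, predict

__all__ = [
    "SurfaceTruth",
    "MetalSpec",
    "generate_bbd_responses",
    "generate_kinetic_trace",
    "rank_by_electronegativity",
]


@dataclass(frozen=True)
class SurfaceTruth:
    """Ground-truth quadratic surface for response-table generation.

    ``coefficients`` follow the canonical 10-term order (intercept,
    linear, squares, interactions); ``sigma`` is the homoscedastic
    response noise in response units.
    """

    coefficients: np.ndarray
    sigma: float = 0.0
    n_center: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, dtype=float))
        if self.sigma < 0:
            raise ValidationError("noise sigma must be >= 0")
        if self.n_center < 1:
            raise ValidationError("n_center must be >= 1")


def generate_bbd_responses(
    truth: SurfaceTruth,
    factors: Sequence[FactorSpec],
    rng: np.random.Generator | None = None,
) -> DesignTable:
    """Build the BBD and draw responses from the truth surface + noise."""
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    design = build_bbd(factors, n_center=truth.n_center)
    model = QuadraticModel(
        factor_names=design.factor_names, coefficients=truth.coefficients
    )
    mean = np.atleast_1d(predict(model, design.coded))
    noise = rng.normal(0.0, truth.sigma, size=mean.shape) if truth.sigma > 0 else 0.0
    return design.with_responses(mean + noise)


def generate_kinetic_trace(
    model: str,
    qe: float,
    k: float,
    c0: float,
    volume_l: float,
    mass_g: float,
    times,
    sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> KineticTrace:
    """Closed-form kinetic trace with Gaussian noise on the concentrations.

    ``model`` is ``"first"`` or ``"second"``.  The mass balance must be
    feasible: the equilibrium uptake ``qe * m / V`` cannot exceed C_0.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    if qe <= 0 or k <= 0 or c0 <= 0 or volume_l <= 0 or mass_g <= 0:
        raise ValidationError("kinetic parameters must all be positive")
    if qe * mass_g / volume_l > c0 + 1e-12:
        raise ValidationError(
            f"infeasible mass balance: qe*m/V = {qe * mass_g / volume_l:.4g} exceeds C_0 = {c0}"
        )
    if model in ("first", "pseudo-first-order"):
        qt = qe * (1.0 - np.exp(-k * t))
    elif model in ("second", "pseudo-second-order"):
        qt = qe**2 * k * t / (1.0 + qe * k * t)
    else:
        raise ValidationError(f"unknown kinetic model {model!r}")
    ct = c0 - mass_g * qt / volume_l
    if sigma > 0:
        ct = ct + rng.normal(0.0, sigma, size=ct.shape)
        ct = np.clip(ct, 0.0, None)
    return KineticTrace(
        times=t,
        concentrations=ct,
        c0=c0,
        volume_l=volume_l,
        mass_g=mass_g,
        c_tolerance=5.0 * sigma,
    )


@dataclass(frozen=True)
class MetalSpec:
    """A metal ion and its Pauling electronegativity."""

    name: str
    electronegativity: float

    def __post_init__(self) -> None:
        if self.electronegativity <= 0:
            raise ValidationError("electronegativity must be > 0")


def rank_by_electronegativity(metals: Sequence[MetalSpec]) -> list[MetalSpec]:
    """Stable descending sort by electronegativity.

    Predicts the qualitative multi-metal removal ordering (the most
    electronegative cation binds best); near-equal electronegativities
    give experimentally comparable efficiencies, so adjacent swaps among
    near ties are expected.
    """
    metals = list(metals)
    if not metals:
        raise ValidationError("cannot rank an empty metal list")
    return sorted(metals, key=lambda m: -m.electronegativity)
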