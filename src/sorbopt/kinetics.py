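"""Adsorption capacities, removal efficiency and kinetic model fits.

Batch biosorption bookkeeping:

    R   = (C_i - C_f) / C_i * 100          removal efficiency, percent
    q_t = V (C_0 - C_t) / m                adsorbed amount, mg per g

and the two classical empirical rate laws in their linearized forms:

    pseudo-first order   log10(q_e - q_t) = log10(q_e) - (k1/ln 10) t
    pseudo-second order  t/q_t = 1/(k2 q_e^2) + t/q_e

The first-order linearization needs the experimental plateau q_e
supplied by the caller (points at or above it have no logarithm and are
excluded); the second-order one is fit on (t, t/q_t).  The familiar
2.303 divisor is ln(10) rounded to four figures; the exact constant is
used so noiseless round trips are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidFitError, ValidationError

__all__ = [
    "KineticTrace",
    "KineticFit",
    "removal_efficiency",
    "qt_series",
    "fit_pseudo_first_order",
    "fit_pseudo_second_order",
]

log = logging.getLogger(__name__)


def removal_efficiency(c_initial: float, c_final) -> float | np.ndarray:
    """Percent of solute removed from solution.

    Negative values (final above initial concentration) are returned but
    logged — they indicate desorption or inconsistent measurements.
    """
    if c_initial <= 0:
        raise ValidationError(f"initial concentration must be > 0, got {c_initial}")
    r = (c_initial - np.asarray(c_final, dtype=float)) / c_initial * 100.0
    if np.any(np.asarray(r) < 0):
        log.warning("removal_efficiency: negative efficiency (C_f > C_i)")
    return float(r) if np.ndim(c_final) == 0 else r


@dataclass
class KineticTrace:
    """A batch kinetic run: residual concentration versus time.

    ``times`` in minutes (strictly increasing, >= 0), concentrations in
    mg/L, ``volume_l`` in litres and ``mass_g`` grams of adsorbent.
    ``c_tolerance`` is the allowance above C_0 granted to measurement
    noise before validation rejects a point.
    """

    times: np.ndarray
    concentrations: np.ndarray
    c0: float
    volume_l: float
    mass_g: float
    c_tolerance: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape or self.times.ndim != 1:
            raise ValidationError("times and concentrations must be equal-length 1-D arrays")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be non-negative and strictly increasing")
        if self.volume_l <= 0 or self.mass_g <= 0:
            raise ValidationError("volume and adsorbent mass must be > 0")
        if self.c0 <= 0:
            raise ValidationError("initial concentration must be > 0")
        if np.any(self.concentrations > self.c0 + self.c_tolerance):
            raise ValidationError("concentrations exceed C_0 beyond the stated tolerance")


def qt_series(trace: KineticTrace) -> np.ndarray:
    """Adsorbed amount per gram at each time: q_t = V (C_0 - C_t) / m."""
    return trace.volume_l * (trace.c0 - trace.concentrations) / trace.mass_g


@dataclass
class KineticFit:
    """Linearized kinetic fit: equilibrium capacity, rate constant, R^2.

    ``rate_constant`` is k1 (1/min) for the first-order model and k2
    (g/mg/min) for the second-order one.  ``n_excluded`` counts points
    dropped from the linearization's domain.
    """

    model: str
    qe_calc: float
    rate_constant: float
    r_squared: float
    qe_exp: float | None = None
    n_used: int = 0
    n_excluded: int = 0


def fit_pseudo_first_order(times, q_t, qe_exp: float) -> KineticFit:
    """Least-squares line on (t, log10(qe_exp - q_t)).

    k1 = -slope * ln(10); qe_calc = 10^intercept.  Points with
    q_t >= qe_exp fall outside the logarithm's domain; they are excluded
    and counted (and logged).  Requires >= 3 usable points.
    """
    t = np.asarray(times, dtype=float)
    q = np.asarray(q_t, dtype=float)
    if qe_exp <= 0:
        raise ValidationError("qe_exp must be > 0")
    usable = q < qe_exp
    n_exc = int(np.sum(~usable))
    if n_exc:
        log.info("fit_pseudo_first_order: excluded %d point(s) with q_t >= qe_exp", n_exc)
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 points with q_t < qe_exp, have {int(usable.sum())}"
        )
    res = stats.linregress(t[usable], np.log10(qe_exp - q[usable]))
    k1 = -res.slope * np.log(10.0)
    if k1 <= 0:
        raise InvalidFitError("non-positive first-order rate constant; model inapplicable")
    return KineticFit(
        model="pseudo-first-order",
        qe_calc=float(10.0 ** res.intercept),
        rate_constant=float(k1),
        r_squared=float(res.rvalue**2),
        qe_exp=float(qe_exp),
        n_used=int(usable.sum()),
        n_excluded=n_exc,
    )


def fit_pseudo_second_order(times, q_t) -> KineticFit:
    """Least-squares line on (t, t/q_t).

    qe_calc = 1/slope and k2 = slope^2 / intercept; both line parameters
    must be positive for the model to apply.  Points with t <= 0 or
    q_t <= 0 are excluded (t/q_t undefined); requires >= 3 usable points.
    """
    t = np.asarray(times, dtype=float)
    q = np.asarray(q_t, dtype=float)
    usable = (t > 0) & (q > 0)
    n_exc = int(np.sum(~usable))
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 points with t > 0 and q_t > 0, have {int(usable.sum())}"
        )
    res = stats.linregress(t[usable], t[usable] / q[usable])
    if res.slope <= 0 or res.intercept <= 0:
        raise InvalidFitError(
            "non-positive slope or intercept in the t/q_t line; "
            "pseudo-second-order model inapplicable"
        )
    return KineticFit(
        model="pseudo-second-order",
        qe_calc=float(1.0 / res.slope),
        rate_constant=float(res.slope**2 / res.intercept),
        r_squared=float(res.rvalue**2),
        n_used=int(usable.sum()),
        n_excluded=n_exc,
    )
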