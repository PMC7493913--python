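"""Packaged reference data for the Pb(II) biosorption case study.

Ships the 15-run Box-Behnken table (pH, temperature, biomass dose versus
percent Pb(II) removal by dried *Chlorella kessleri* biomass) together
with the published reference values derived from it: the fitted
second-order coefficients, the per-run model predictions, the
multi-metal electronegativity list and the kinetic parameters of the
published pseudo-first/second-order fits.  The printed constants serve
as fixtures for regression tests and synthetic-data truth models; all
analyses in the package recompute them from the table.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .design import DesignTable, FactorSpec, read_design
from .rsm import QuadraticModel
from .synthetic import MetalSpec

__all__ = [
    "PB_FACTORS",
    "PB_REFERENCE_COEFFICIENTS",
    "PB_REFERENCE_PREDICTED",
    "PB_DF_OPTIMUM_CODED",
    "PB_DF_OPTIMUM_RESPONSE",
    "PB_DF_COMPOSITE_DESIRABILITY",
    "PB_CSA_OPTIMUM_CODED",
    "PB_CSA_BEST_FITNESS",
    "PB_KINETIC_PARAMETERS",
    "HEAVY_METALS",
    "load_pb_design",
    "pb_reference_model",
]

#: Factor ranges of the Pb(II) study (low, high); centres are midpoints.
PB_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("pH", 4.0, 8.0),
    FactorSpec("temperature", 20.0, 40.0),
    FactorSpec("dose", 0.5, 1.5),
)

#: Published coded-model coefficients, canonical term order
#: (Intercept, pH, T, dose, pH^2, T^2, dose^2, pH*T, pH*dose, T*dose).
PB_REFERENCE_COEFFICIENTS = np.array(
    [94.65, 6.101, -2.180, 7.238, -11.24, -3.55, -2.84, -0.905, -2.401, 0.713]
)

#: Published per-run model predictions, aligned with the fixture rows.
PB_REFERENCE_PREDICTED = np.array(
    [82.88, 81.83, 94.65, 89.05, 94.03, 83.91, 84.11, 78.13, 94.65, 96.96,
     94.65, 72.49, 75.04, 64.83, 91.51]
)

#: Published profile-optimizer (desirability) optimum and its scores.
PB_DF_OPTIMUM_CODED = np.array([0.1717, -0.2323, 1.0])
PB_DF_OPTIMUM_RESPONSE = 99.5373
PB_DF_COMPOSITE_DESIRABILITY = 0.9868

#: Published crow-search optimum over the same fitted surface.
PB_CSA_OPTIMUM_CODED = np.array([0.1739, -0.2288, 0.9999])
PB_CSA_BEST_FITNESS = 99.537002

#: Published kinetic fit parameters (mg/g, 1/min, g/mg/min).
PB_KINETIC_PARAMETERS = {
    "qe_exp": 3.727,
    "first": {"qe_calc": 0.966, "k1": 0.0879},
    "second": {"qe_calc": 3.782, "k2": 0.1148},
}

#: The five study metals with their Pauling electronegativities.
HEAVY_METALS: tuple[MetalSpec, ...] = (
    MetalSpec("Pb", 2.33),
    MetalSpec("Cu", 1.90),
    MetalSpec("Co", 1.88),
    MetalSpec("Cd", 1.69),
    MetalSpec("Cr", 1.66),
)


def load_pb_design() -> DesignTable:
    """The packaged 15-run Pb(II) design/response table."""
    path = resources.files("sorbopt") / "data" / "pb_bbd.csv"
    with resources.as_file(path) as p:
        return read_design(p, factors=PB_FACTORS)


def pb_reference_model() -> QuadraticModel:
    """Quadratic model built from the published (rounded) coefficients.

    Carries no residual information — use :func:`sorbopt.rsm.fit_quadratic`
    on :func:`load_pb_design` for inference-grade refits.
    """
    return QuadraticModel(
        factor_names=tuple(f.name for f in PB_FACTORS),
        coefficients=PB_REFERENCE_COEFFICIENTS.copy(),
    )
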