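"""Parameter recovery on synthetic response tables.

Simulates Box-Behnken experiments from a known quadratic surface at the
case study's residual noise level and refits each one: the average
refitted coefficients should sit on the truth (least squares is
unbiased), and the pure-error mean square should estimate the injected
noise variance.
"""

import numpy as np

from sorbopt import SurfaceTruth, anova, fit_quadratic, generate_bbd_responses
from sorbopt.datasets import PB_FACTORS, PB_REFERENCE_COEFFICIENTS
from sorbopt.rsm import term_names

sigma = 1.93  # ~ sqrt of the case study's error mean square
truth = SurfaceTruth(PB_REFERENCE_COEFFICIENTS, sigma=sigma)
rng = np.random.default_rng(0)

coefs, pe_ms = [], []
for _ in range(200):
    table = generate_bbd_responses(truth, PB_FACTORS, rng=rng)
    model, _ = fit_quadratic(table)
    coefs.append(model.coefficients)
    pe_ms.append(anova(model, table)["Pure Error"].adj_ms)

mean_coef = np.mean(coefs, axis=0)
print(f"{'term':>24s} {'truth':>8s} {'mean refit':>11s}")
for term, t, m in zip(term_names([f.name for f in PB_FACTORS]),
                      PB_REFERENCE_COEFFICIENTS, mean_coef):
    print(f"{term:>24s} {t:8.3f} {m:11.3f}")
print(f"\nmean pure-error MS = {np.mean(pe_ms):.3f} (injected sigma^2 = {sigma**2:.3f})")
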