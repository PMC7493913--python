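"""Fit the quadratic surface to the packaged Pb(II) table and inspect it.

Loads the 15-run Box-Behnken experiment (pH, temperature, biomass dose
versus percent Pb(II) removal), fits the full second-order model by
least squares, and prints the coefficients, the ANOVA with the
lack-of-fit split, and the standardized-effect ranking.  Large |t|
values mark the terms that drive removal efficiency.
"""

from sorbopt import anova, fit_quadratic, standardized_effects
from sorbopt.datasets import load_pb_design

design = load_pb_design()
model, summary = fit_quadratic(design)

print("fitted coefficients (coded units):")
for term, coef in model.coef.items():
    print(f"  {term:>24s}  {coef: .4f}")
print(f"R^2 = {summary.r_squared:.4f}, adjusted R^2 = {summary.adj_r_squared:.4f}\n")

print(anova(model, design).to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))

effects = standardized_effects(model)
print(f"\nstandardized effects (|t| ranking, threshold {effects.threshold:.3f}):")
for row in effects.rows:
    mark = "*" if row.significant else " "
    print(f"  {mark} {row.term:>24s}  t = {row.t:8.3f}")
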