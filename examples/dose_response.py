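"""Growth inhibition and IC50 from cell-density endpoints.

Feeds the dose-response layer with a synthetic exposure trial: endpoint cell
densities that decline with dose following a log-logistic curve with a known
IC50, then recovers that IC50 by least squares.
"""

import numpy as np

from ojiptox.doseresp import DoseResponseSeries, fit_ic50, growth_inhibition

true_ic50, hill = 120.0, 1.8
control_density = 2.7e5  # cells/mL, the assay's initial-density convention
doses = np.array([0.0, 10.0, 30.0, 100.0, 300.0, 1000.0])

frac = np.where(doses > 0, doses**hill / (doses**hill + true_ic50**hill), 0.0)
treatment_density = control_density * (1 - frac)
treatment_density[0] = control_density

inh = growth_inhibition(treatment_density, control_density)
series = DoseResponseSeries("demo", tuple(doses), tuple(inh))
fit = fit_ic50(series)

print("dose (ug/L)   growth inhibition (%)")
for d, i in zip(doses, inh):
    print(f"{d:>10.0f}   {i:+8.1f}")
print(f"\nfitted IC50 = {fit.ic50:.1f} ug/L (true {true_ic50}), "
      f"hill = {fit.hill:.2f} (true {hill})")
print(f"converged={fit.converged}, extrapolated={fit.extrapolated}")
print("negative inhibition means the culture grew less than its control; "
      "IC50 is the dose at 50% inhibition")
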