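"""Diffusion coefficient from a scan-rate study and micro-interface sizing.

A scan-rate series generated by the reversible peak-current relation (with
2% multiplicative noise) is inverted back to the diffusion coefficient, and
a measured steady-state current sizes a capillary-supported interface.
"""

import numpy as np

from itieskit import (
    diffusion_from_scan_rate_series,
    randles_sevcik_peak_current,
    saito_current,
    saito_radius,
)

rng = np.random.default_rng(0)
d_true = 11.2e-6  # cm^2/s
area, conc = 1.327, 2e-8  # cm^2, mol/cm^3 (20 uM)
rates = np.array([0.005, 0.01, 0.02, 0.04, 0.08])  # V/s
peaks = np.array(
    [randles_sevcik_peak_current(1, area, conc, d_true, v) for v in rates]
)
noisy = peaks * (1 + rng.normal(0, 0.02, peaks.size))
fit = diffusion_from_scan_rate_series(
    np.column_stack([rates, noisy]), charge=1, area=area, concentration=conc
)
print(f"true D = {d_true:.3g} cm^2/s, recovered D = {fit.diffusion:.3g} cm^2/s"
      f" (R^2 = {fit.r_squared:.4f})")

iss = saito_current(radius=12e-4, charge=1, diffusion=13.8e-6, concentration=5e-8)
print(f"steady-state current for a 12 um radius interface: {iss * 1e9:.3f} nA")
r = saito_radius(iss, charge=1, diffusion=13.8e-6, concentration=5e-8)
print(f"inverting that current returns r = {r * 1e4:.1f} um"
      " - the routine capillary quality-control check")
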