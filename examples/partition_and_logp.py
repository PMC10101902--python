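"""Ion-partition diagram fitting and lipophilicity extraction.

Generates a synthetic (pH, apparent transfer potential) series from a known
boundary-line model with 2 mV noise, refits the distribution constant KD of
the neutral form, and converts the formal transfer potentials of both drug
cations into water/1,2-DCE partition coefficients.
"""

from itieskit import (
    IonPartitionModel,
    fit_partition_model,
    logp_from_potential,
    mechanism_at,
    nitrazepam,
    simulate_ph_series,
)

truth = IonPartitionModel(formal_potential=0.242, pka=3.2, kd=10.0)
series = simulate_ph_series(
    nitrazepam(), truth, [2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5],
    potential_noise_sd=0.002, seed=1,
)
points = [(p.ph, p.observed_potential) for p in series]
fit = fit_partition_model(points, pka=3.2)
print(f"true KD = 10, fitted KD = {fit.kd:.2f} +/- {fit.kd_stderr:.2f}")
print(f"fitted formal potential = {fit.formal_potential * 1e3:.1f} mV")

for name, phi in (("7-aminonitrazepam(+)", 0.150), ("nitrazepam(+)", 0.242)):
    logp = logp_from_potential(phi, 1)
    print(f"{name}: formal potential {phi * 1e3:.0f} mV -> logP = {logp:.2f}")
print("(more positive transfer potential = harder to push into the organic"
      " phase = more negative logP)")

metabolite = IonPartitionModel(formal_potential=0.150, pka=4.6, kd=0.1)
for ph in (3.0, 6.0):
    print(f"7-aminonitrazepam at pH {ph:.1f}: "
          f"{mechanism_at(metabolite, ph).value}")
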