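# itieskit

Electroanalysis of ionizable drugs at electrified liquid–liquid interfaces
(ITIES — the interface between two immiscible electrolyte solutions), built
for electrochemists and forensic/pharmaceutical analysts who extract
physicochemical and analytical parameters from ion-transfer voltammetry
(ITV).  The worked systems throughout are the benzodiazepines nitrazepam
(NIT) and its metabolite 7-aminonitrazepam (7a-NIT) partitioning between
water and 1,2-dichloroethane, but every routine takes user-supplied
parameters.

## What it computes

**Speciation.** For a ladder of acid dissociation constants
pKa₁ < … < pKaₙ, the concentration fraction of the k-th microspecies is

    x_k(pH) = w_k / Σ_m w_m ,   w_k = 10^( Σ_{j≤k} (pH − pKa_j) ),

evaluated in log space.  Dominance ranges split the pH axis at the pKa's.

**Ion-partition diagrams.** The boundary line of the cation/neutral branch,

    Δφ(pH) = Δφ°′ + (RT/F)·ln(1 + 10^(pH−pKa)·(1 + K_D)),

is flat where the drug transfers as a simple cation and rises ~59 mV/pH
where facilitated proton transfer by the partitioned neutral base takes
over.  K_D (distribution constant of the neutral form, org/aq) is fitted by
least squares on a log₁₀ scale; the partition coefficient of the ion
follows from logP = −Δφ°′·z·F/(2.303·RT).

**Transport.** The reversible peak current I_p = 0.4463·zFAC·√(zFνD/RT)
(Randles–Ševčík) is inverted through an I_p vs √ν regression to obtain D;
the micro-interface steady-state current I_ss = 4zFDCr (Saito) is inverted
to size capillary-supported interfaces.

**Signal processing.** Triangular-sweep segmentation, straight-line
baselines, forward/backward peak pairs, steady-state waves, internal
reference-ion potential correction, potential-window width of blanks, and
3σ binary presence calls for complex matrices.

**Quantification.** OLS calibrations with LOD = 3σ/a and LOQ = 10σ/a
(σ = standard error of the intercept), area-normalized sensitivities,
standard-addition quantification with dilution-chain back-calculation
(optionally volume-corrected per addition), recovery and RSD.

**Synthetic voltammograms.** A finite-difference simulator (Nernstian
partition condition at the interface, diffusion in both phases) generates
macroscopic cyclic ITVs; a hybrid steady-state/pore-diffusion model
generates microscopic wave/peak ITVs; plus pH-series, calibration and
standard-addition tables — so the full pipeline runs and is tested with no
instrument attached.

## Worked example

```python
from itieskit import (CellGeometry, logp_from_potential, normalize_sensitivity,
                      standard_addition)
import numpy as np

# lipophilicity from formal transfer potentials (z = +1, 293.15 K)
logp_from_potential(0.150, 1)   # -> -2.58  (7a-NIT+)
logp_from_potential(0.242, 1)   # -> -4.16  (NIT+)

# macroscopic sensitivity normalized by the 0.65 cm radius interface
normalize_sensitivity(0.105, CellGeometry("macro", 0.65))  # -> 0.079 A/(M cm^2)

# tablet assay from a standard-addition response line (nA vs uM)
added = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
signal = 0.0128 * added + 0.1941
res = standard_addition(np.column_stack([added * 1e-6, signal * 1e-9]),
                        dilution_factor=50.0, stock_volume=0.025,
                        molar_mass=281.27, volume_correction=False)
res.x_intercept_concentration * 1e6   # -> 15.16 uM in the droplet
res.content_mass * 1e3                # -> 5.33 mg in the tablet
```

The logP values say both cations strongly prefer water (NIT⁺ more so); the
15.16 µM intercept is the drug concentration in the measured droplet, and
the dilution chain (×50, 25 mL, 281.27 g/mol) turns it into the tablet's
milligram content.

The `examples/` directory holds one short script per capability
(speciation diagrams, partition fitting, transport estimation, macro and
micro simulation with extraction, calibration/LOD, tablet quantification,
biofluid presence calls); each prints the numbers it computes with a line
on what they mean.

A thin CLI wraps the same stages for batch use:
`itieskit simulate -c config.yaml`, then `itieskit peaks -c config.yaml`,
etc.; see `itieskit --help`.

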