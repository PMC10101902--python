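# Methods

This note documents the models behind `itieskit`, the defaults and why
they were chosen, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Physical setting

At a polarizable liquid–liquid interface the controlled variable is the
Galvani potential difference Δφ between the aqueous and organic bulk
phases, and the measured current is carried by ions crossing the
interface.  A protonatable drug appears in several microspecies whose
populations follow the acid–base ladder; which species carries the current
— and at what potential — depends on pH, on the formal transfer potential
Δφ°′ of the ion, and on the distribution constant K_D of the neutral form.

## Conditions and constants

All potential ↔ energy conversions go through one `Conditions` object
(R = 8.314 J mol⁻¹ K⁻¹, F = 96485 C mol⁻¹, temperature in kelvin,
validated to [270, 330] K).  The default temperature is **293.15 K**
(20 °C, a typical unthermostatted-lab value); at this temperature the two
worked formal potentials 150 mV and 242 mV map to logP = −2.58 and −4.16
exactly, whereas 298.15 K would give −2.54 and −4.09.  Temperature is a
parameter everywhere and is echoed into every serialized result.

## Speciation

Fractions are computed from cumulative deprotonation weights in log space
(`logsumexp`), so diagrams remain exact arbitrarily far from every pKa
(naive 10^x forms overflow beyond |pH − pKa| ≈ 15).  Validation enforces a
strictly ascending pKa ladder and a charge ladder that decreases by
exactly one per deprotonation.  Activity corrections, ionic-strength
effects and the temperature dependence of pKa are out of scope.  The
bundled nitrazepam ladder uses pKa 3.2/10.8 and the 7-aminonitrazepam
ladder 2.5/4.6/13.1 — literature values offered as defaults only; the
reported alternatives (10.6 for the azomethine step of nitrazepam, 4.8 for
the amine step of the metabolite) can simply be passed in.

## Partition boundary and K_D fitting

The boundary line is implemented as
Δφ(pH) = Δφ°′ + (RT/F)·ln(1 + 10^(pH−pKa)(1+K_D)) via `logaddexp`.  The
natural-logarithm form is fixed by dimensional analysis and by the
observed Nernstian (~58 mV/pH at 293 K) slope of the facilitated-transfer
regime.  **K_D convention:** org/aq — a larger K_D means a more lipophilic
neutral form.  Verbal definitions in the literature sometimes read as
aq/org while the fitted magnitudes imply org/aq; this package documents
and tests one convention rather than guessing intent.

Fitting: nonlinear least squares over log₁₀K_D (positivity and
scale-freeness) and optionally Δφ°′, initialised at K_D = 1 and at the
mean observed potential of points with pH ≤ pKa − 1 (the plateau); at
least one point below the pKa is required when the plateau is free.
Standard errors come from the Gauss–Newton covariance (JᵀJ)⁻¹·SSR/(n−p),
delta-method-propagated to the linear K_D scale.  The mechanism
classifier calls a point simple ion transfer while
10^(pH−pKa)(1+K_D) < 1 and facilitated proton transfer at or above the
crossover (tie broken upward, documented in the API).

## Transport

The Randles–Ševčík inversion uses the reversible dimensionless peak factor
0.4463; quasi-reversible corrections are out of scope.  D comes from the
slope of an OLS fit of I_p on √ν with a **free intercept** kept as a
diagnostic — experimental series rarely pass through the origin, and
forcing them through would bias D.  The Saito inversion r = I_ss/(4zFDC)
is exact algebra; its roundtrip with the forward formula is tested to
1e−14.  The module works in CGS-molar units (cm, cm², cm² s⁻¹, mol cm⁻³)
because diffusion coefficients are conventionally quoted that way;
µM/µA/nA conversions live in `itieskit.units`.

## Signal processing

* **Segmentation** splits at the first potential extremum; multi-cycle
  programs use the first cycle with a warning; monotone or constant
  programs are errors.
* **Baseline** is a straight line fitted to the 30% of the sweep samples
  immediately preceding the search window (method name recorded in every
  `PeakMeasurement`).  No published baseline convention exists for these
  cells; a pre-peak line is the common manual practice.
* **Noise** is estimated robustly as 1.4826 × median absolute deviation.
  Peak extraction applies it to the detrended baseline region; the
  potential-window and presence-call routines apply it to first
  differences (÷√2), which is insensitive to the smooth exponential walls
  and capacitive offset.
* **Peaks** must exceed 3× the local noise SD or a `NoPeakError` is
  raised — this error is the "absent" pathway of the qualitative call.
* **Waves**: I_ss is the mean baseline-corrected forward current over the
  plateau window; windows sloping more than 10% of I_ss per 100 mV are
  rejected as non-plateaus.  The half-wave potential is the first upward
  crossing of I_ss/2 (linear interpolation).
* **Reference correction** shifts the potential axis so the measured
  midpoint of an internal reference ion (TMA⁺/TPrA⁺) lands on its assigned
  formal potential; currents are untouched and the applied shift is
  accumulated in the metadata.
* **Presence calls** subtract the (resampled) blank and ask whether the
  maximum within expected ± tolerance exceeds 3× the blank's local noise.
  This is a screening heuristic — matrix effects make real-sample data
  qualitative — and is monotone in spike amplitude by construction.
* Optional five-point adjacent averaging is available for the noisier
  micro traces and is off by default for macro data.

## Calibration and quantification

σ in the 3σ/a detection limit is the **standard error of the OLS
intercept** (the common reading of "standard deviation of the intercept");
LOQ uses 10σ/a.  Fits are plain OLS — no weighting, no outlier handling —
with replicate aggregation by mean and RSD, matching routine
electroanalytical practice.  Area normalization always divides by a
caller-supplied circular geometry; no nominal radius is ever substituted
silently, because published radii for nominally identical supports are
inconsistent.

Standard addition extrapolates the response line to its x-axis crossing;
the measured-cell concentration is then scaled by the dilution factor,
stock volume and molar mass.  Two conventions are implemented and
labelled: `volume_correction=False` takes the supplied added
concentrations at face value (appropriate when re-analysing a published
line), while `volume_correction=True` (default for new analyses)
recomputes x_k = C_std·k·ΔV/V₀ and scales signals by (V₀+k·ΔV)/V₀ from an
`AdditionScheme` (default: 10 µL droplet, 2.5 µL spikes of an 80 µM
standard), making the quantification exact under droplet growth.  The two
conventions differ by several percent for µL-scale droplets — enough to
explain small discrepancies between printed intercepts and printed tablet
contents, which is why the convention is always carried in the result.

## Synthetic voltammograms

The generator replaces the potentiostat so every stage is testable
offline; its defaults are the study conditions of the worked system
(20 mV/s scans, 10–30 µM analytes, 0.65 cm macro radius, 12–12.5 µm micro
radius, walls closing an ~0.8 V window).

**Macro solver.** 1-D semi-infinite diffusion in both phases, explicit
FTCS with reflecting far boundaries, domain length 6·√(D·t_total),
default 400 nodes, stability factor λ = D·Δt/Δx² = 0.45 (rejected above
0.5 before any computation).  The interface node satisfies the Nernstian
partition ratio c_org(0)/c_aq(0) = exp[zF(Δφ−Δφ°′)/RT] together with flux
continuity, both discretized with one-sided three-point derivatives; the
current is zFA times the interfacial flux.  Verification: the forward
peak current agrees with the Randles–Ševčík value to 0.01% at default
resolution, the peak separation approaches the reversible 2.218·RT/F
within 1 mV (the small residual is the physical switching-potential
dependence, not discretization), total mass is conserved to ~1e−15
relative, and doubling the grid changes the peak current by < 0.01%.

**Micro solver.** One hybrid scheme produces the experimental asymmetry:
the aqueous side supplies ions through a steady-state mass-transfer
coefficient m = I_ss/(zFAC) whose limiting current is exactly the Saito
value; the organic side is explicit 1-D diffusion inside the capillary
pore (closed far end at ten pore diameters, default 120 nodes).  The mouth
flux solves the series combination of the Nernst condition, the aqueous
supply and the half-box film conductance in an overflow-safe form.
Forward sweep: a semi-sigmoidal wave with plateau = Saito current (within
~1.5%; the small deficit is back-pressure from ion accumulated in the
pore).  Backward sweep: the accumulated charge returns as a clear
diffusional peak.  The true 3-D pore/bulk geometry, adsorption and
uncompensated resistance are not modelled.

**Backgrounds and noise.** Walls follow
A_w·[exp((Δφ−φ₊)/β) − exp(−(Δφ−φ₋)/β)] with β = 25 mV and default onsets
−0.25/+0.55 V (model electrolytes; +0.40 V mimics a biofluid's shrunken
window), plus a scan-direction capacitive term c_dl·ν·A (c_dl = 10 µF/cm²).
These are phenomenological stand-ins for supporting-electrolyte transfer,
not fitted to any instrument.  Noise is Gaussian; the defaults (0.05 µA
macro, 5 pA micro) are figure-scale magnitudes, configurable, and every
stochastic output is bitwise-reproducible from its seed.

**pH series.** Apparent transfer potentials follow the boundary line plus
optional noise; a point is flagged undetectable when its peak would sit
within 0.10 V of the positive wall, which reproduces the experimentally
observed loss of the nitrazepam signal above pH ≈ 5 as the facilitated
branch climbs into the background.

## What passing tests do and do not show

The generator shares the analysis modules' forward models (by design: the
closed forms are the oracles), so recovery tests demonstrate correctness
of the inversions and robustness to Gaussian noise at stated levels — not
robustness to adsorption, iR drop, drift, or real matrix chemistry, none
of which the generator emulates.  Real-sample presence calls remain a
heuristic and are treated as such.

## Problem sizes

Default test problem sizes: 400–800 spatial nodes (≈10⁴–4·10⁴ time steps)
for macro simulations, 120 nodes for micro; 50 replicates for K_D
recovery at 2 mV potential noise, 100 for D at 2% current noise, 500 for
the LOD calibration study.  These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances.
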