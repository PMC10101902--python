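"""Acid-base speciation of nitrazepam and 7-aminonitrazepam.

Builds the two protolytic ladders, prints which microspecies dominates in
which pH range, and evaluates the concentration fractions at a few
physiologically relevant pH values.  The low-pH fractions explain why the
drugs are detectable as cations in acidified aqueous phases.
"""

from itieskit import (
    dominance_ranges,
    fraction_of,
    nitrazepam,
    seven_aminonitrazepam,
    species_fractions,
)

for system in (nitrazepam(), seven_aminonitrazepam()):
    print(f"\n{system.name} (pKa = {', '.join(map(str, system.pka_values))})")
    for label, lo, hi in dominance_ranges(system):
        print(f"  {label:>9s} dominates for {lo:5.1f} < pH < {hi:5.1f}")
    for ph in (2.0, 4.0, 7.0):
        fracs = species_fractions(system, ph)
        parts = ", ".join(
            f"{lab} {f:.3f}" for lab, f in zip(system.species_labels, fracs)
        )
        print(f"  pH {ph:.1f}: {parts}")

frac = fraction_of(seven_aminonitrazepam(), "dication", 2.0)
print(
    f"\nAt pH 2.0 the 7-aminonitrazepam dication holds a fraction of {frac:.3f}"
    " of the dissolved drug - the monocation still dominates the ion-transfer"
    " signal because the dication is the less lipophilic species."
)
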