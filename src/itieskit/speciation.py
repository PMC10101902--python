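"""Multi-pKa acid-base speciation for ionizable drugs.

A polyprotic molecule with acid dissociation exponents ``pKa_1 < ... < pKa_n``
occurs as ``n+1`` microspecies, from the most protonated (lowest pH) to the
least.  Writing the cumulative deprotonation weight of species ``k`` as

    w_k(pH) = 10 ** sum_{j<=k} (pH - pKa_j),        w_0 = 1,

the equilibrium concentration fraction of species ``k`` is
``w_k / sum_m w_m``.  Fractions are evaluated with a log-sum-exp so the
diagram stays finite arbitrarily far from every pKa.

For the benzodiazepines this package was written around, nitrazepam carries
pKa 3.2 (ring nitrogen) and 10.8 (azomethine), giving cation/neutral/anion
ranges; its metabolite 7-aminonitrazepam adds a primary-amine step at 4.6
between ring (2.5) and azomethine (13.1) protonation, giving a dication at
low pH.  Those literature ladders are offered as conveniences
(:func:`nitrazepam`, :func:`seven_aminonitrazepam`) but every pKa is
user-supplied data, never an internal constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .conditions import LN10
from .errors import InvalidInputError

__all__ = [
    "ProtolyticSystem",
    "species_fractions",
    "dominance_ranges",
    "fraction_of",
    "nitrazepam",
    "seven_aminonitrazepam",
]


@dataclass(frozen=True)
class ProtolyticSystem:
    """An ordered ladder of acid-base equilibria.

    Parameters
    ----------
    name:
        Identifier of the compound, e.g. ``"nitrazepam"``.
    pka_values:
        Acid dissociation exponents, strictly ascending.  ``Ka_i = 10**-pKa_i``.
    species_charges:
        Integer charge of each microspecies, ordered from most protonated to
        least; one entry more than ``pka_values``, and each step down the
        ladder removes exactly one proton (charge decreases by one).
    species_labels:
        One label per microspecies (e.g. ``("cation", "neutral", "anion")``).
    molar_mass:
        Optional molar mass in g/mol, used by quantification stages.
    """

    name: str
    pka_values: tuple[float, ...]
    species_charges: tuple[int, ...]
    species_labels: tuple[str, ...]
    molar_mass: float | None = None

    def __init__(
        self,
        name: str,
        pka_values: Sequence[float],
        species_charges: Sequence[int],
        species_labels: Sequence[str],
        molar_mass: float | None = None,
    ) -> None:
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "pka_values", tuple(float(p) for p in pka_values))
        object.__setattr__(self, "species_charges", tuple(int(z) for z in species_charges))
        object.__setattr__(self, "species_labels", tuple(str(s) for s in species_labels))
        object.__setattr__(self, "molar_mass", None if molar_mass is None else float(molar_mass))
        self._validate()

    def _validate(self) -> None:
        pka = self.pka_values
        if len(pka) < 1:
            raise InvalidInputError("at least one pKa is required")
        if any(not math.isfinite(p) for p in pka):
            raise InvalidInputError("pKa values must be finite")
        if any(b <= a for a, b in zip(pka, pka[1:])):
            raise InvalidInputError(f"pKa values must be strictly ascending, got {pka}")
        if len(self.species_charges) != len(pka) + 1:
            raise InvalidInputError(
                "need exactly len(pka_values)+1 species charges "
                f"({len(pka) + 1}), got {len(self.species_charges)}"
            )
        if len(self.species_labels) != len(self.species_charges):
            raise InvalidInputError("one label per species is required")
        if len(set(self.species_labels)) != len(self.species_labels):
            raise InvalidInputError("species labels must be unique")
        for a, b in zip(self.species_charges, self.species_charges[1:]):
            if b != a - 1:
                raise InvalidInputError(
                    "each deprotonation must lower the charge by exactly one; "
                    f"got ladder {self.species_charges}"
                )

    @property
    def n_species(self) -> int:
        return len(self.species_labels)

    def index_of(self, species_label: str) -> int:
        try:
            return self.species_labels.index(species_label)
        except ValueError:
            raise LookupError(
                f"unknown species {species_label!r} for {self.name!r}; "
                f"known: {self.species_labels}"
            ) from None

    def label_of_charge(self, charge: int) -> str:
        """Label of the (unique) species carrying ``charge``."""
        try:
            return self.species_labels[self.species_charges.index(charge)]
        except ValueError:
            raise LookupError(
                f"no species of {self.name!r} carries charge {charge:+d}"
            ) from None


def species_fractions(system: ProtolyticSystem, ph: float) -> np.ndarray:
    """Equilibrium concentration fraction of every microspecies at ``ph``.

    Returns an array ordered like ``system.species_labels``; entries lie in
    [0, 1] and sum to one to machine precision.  Evaluated in log space, so
    it is overflow-safe even 100 pH units from the nearest pKa.
    """
    ph = float(ph)
    if not math.isfinite(ph):
        raise InvalidInputError(f"pH must be finite, got {ph!r}")
    pka = np.asarray(system.pka_values)
    # log10 cumulative deprotonation weights, most-protonated species first
    log_w = np.concatenate([[0.0], np.cumsum(ph - pka)])
    ln_w = LN10 * log_w
    fractions = np.exp(ln_w - logsumexp(ln_w))
    return fractions


def fraction_of(system: ProtolyticSystem, species_label: str, ph: float) -> float:
    """Concentration fraction of one named microspecies at ``ph``."""
    return float(species_fractions(system, ph)[system.index_of(species_label)])


def dominance_ranges(
    system: ProtolyticSystem,
) -> list[tuple[str, float, float]]:
    """pH ranges in which each microspecies dominates.

    Returns ``(label, ph_low, ph_high)`` triples that partition
    (-inf, +inf) contiguously with the boundaries at the pKa values: a
    species is the majority form strictly between its flanking pKa's.
    """
    bounds = (-math.inf, *system.pka_values, math.inf)
    return [
        (label, bounds[i], bounds[i + 1])
        for i, label in enumerate(system.species_labels)
    ]


def nitrazepam(
    pka_values: Sequence[float] = (3.2, 10.8),
    molar_mass: float = 281.27,
) -> ProtolyticSystem:
    """Nitrazepam ladder: monocation / neutral / monoanion.

    Literature values place the ring-nitrogen protonation at pKa 3.2 and
    the azomethine deprotonation at 10.8 (10.6 is also reported; pass your
    preferred value).
    """
    return ProtolyticSystem(
        name="nitrazepam",
        pka_values=pka_values,
        species_charges=(1, 0, -1),
        species_labels=("cation", "neutral", "anion"),
        molar_mass=molar_mass,
    )


def seven_aminonitrazepam(
    pka_values: Sequence[float] = (2.5, 4.6, 13.1),
    molar_mass: float = 251.28,
) -> ProtolyticSystem:
    """7-aminonitrazepam ladder: dication / monocation / neutral / monoanion."""
    return ProtolyticSystem(
        name="7-aminonitrazepam",
        pka_values=pka_values,
        species_charges=(2, 1, 0, -1),
        species_labels=("dication", "cation", "neutral", "anion"),
        molar_mass=molar_mass,
    )
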