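"""Solution speciation: neutral fractions and tautomer populations.

Purines are weak acids (and bases); near the crystallization pH only the
uncharged molecule incorporates into the crystal.  The neutral fraction
follows the Henderson–Hasselbalch partition

    f = 1 / (1 + 10^(pH - pKa_acid) + 10^(pKa_base - pH)),

omitting terms whose pKa is not supplied.  Tautomer populations are
Boltzmann weights of the relative energies; the effective available
fraction is the neutral fraction times the weight of the tautomer whose
H-bonding arrangement matches the host lattice.

pKa values and tautomer energies are configuration, not constants: the
shipped fixture uses literature pKa values (guanine 9.4/3.3, hypoxanthine
8.94, xanthine 7.44) and qualitative tautomer-energy placeholders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ArgumentError

R_KJ = 8.314e-3  # kJ mol^-1 K^-1


@dataclass(frozen=True)
class Tautomer:
    name: str
    rel_energy: float  # kJ/mol relative to the most stable tautomer
    crystal_compatible: bool = False


@dataclass(frozen=True)
class SpeciationInput:
    species: str
    pH: float
    pKa_acid: float | None = None  # deprotonation (neutral -> anion)
    pKa_base: float | None = None  # protonation (cation -> neutral)
    tautomers: tuple[Tautomer, ...] = ()

    def __post_init__(self) -> None:
        if (self.pKa_acid is not None and self.pKa_base is not None
                and not self.pKa_base < self.pKa_acid):
            raise ArgumentError("pKa_base must be below pKa_acid")
        if self.tautomers and min(t.rel_energy for t in self.tautomers) != 0.0:
            raise ArgumentError("tautomer energies need a zero reference")


def neutral_fraction(inp: SpeciationInput) -> float:
    """Fraction of uncharged molecules at the input pH."""
    if not 0.0 < inp.pH < 14.0:
        raise ArgumentError("pH must be in (0, 14)")
    if inp.pKa_acid is None and inp.pKa_base is None:
        raise ArgumentError(f"no pKa provided for {inp.species}")
    denom = 1.0
    if inp.pKa_acid is not None:
        denom += 10.0 ** (inp.pH - inp.pKa_acid)
    if inp.pKa_base is not None:
        denom += 10.0 ** (inp.pKa_base - inp.pH)
    return 1.0 / denom


def tautomer_weights(inp: SpeciationInput, T: float = 300.0
                     ) -> dict[str, float]:
    """Boltzmann populations of the tautomer set at temperature T (K)."""
    if T <= 0:
        raise ArgumentError("temperature must be > 0")
    if not inp.tautomers:
        raise ArgumentError(f"no tautomers provided for {inp.species}")
    z = [math.exp(-t.rel_energy / (R_KJ * T)) for t in inp.tautomers]
    total = sum(z)
    return {t.name: w / total for t, w in zip(inp.tautomers, z)}


@dataclass(frozen=True)
class SpeciationProfile:
    species: str
    neutral: float
    weights: dict[str, float] = field(hash=False)
    effective_available: float = 0.0


def speciation_profile(inp: SpeciationInput, T: float = 300.0
                       ) -> SpeciationProfile:
    """Neutral fraction x crystal-compatible tautomer weight."""
    f = neutral_fraction(inp)
    w = tautomer_weights(inp, T) if inp.tautomers else {}
    compat = sum(w[t.name] for t in inp.tautomers if t.crystal_compatible)
    return SpeciationProfile(inp.species, f, w, f * compat)


# ---------------------------------------------------------------------------
# Fixture configuration (literature pKa values; tautomer energies are
# qualitative placeholders ordered per gas/water DFT statements, not
# digitized figure values).

FIXTURE_SPECIES: dict[str, dict] = {
    "guanine": {
        "pKa_acid": 9.4, "pKa_base": 3.3,
        "tautomers": (
            Tautomer("keto-N7H", 0.0, crystal_compatible=True),
            Tautomer("keto-N9H", 2.0),
        ),
    },
    "hypoxanthine": {
        "pKa_acid": 8.94, "pKa_base": 1.98,
        "tautomers": (
            # the lattice-compatible keto-N7H form is also the most stable
            Tautomer("keto-N7H", 0.0, crystal_compatible=True),
            Tautomer("keto-N9H", 2.5),
        ),
    },
    "xanthine": {
        "pKa_acid": 7.44, "pKa_base": 0.8,
        "tautomers": (
            # the lattice-compatible keto-enol-N7H form is a high-energy form
            Tautomer("diketo-N7H", 0.0),
            Tautomer("keto-enol-N7H", 28.0, crystal_compatible=True),
        ),
    },
}


def fixture_input(species: str, pH: float = 9.0) -> SpeciationInput:
    try:
        cfg = FIXTURE_SPECIES[species]
    except KeyError:
        raise ArgumentError(f"unknown species {species!r}; have "
                            f"{sorted(FIXTURE_SPECIES)}") from None
    return SpeciationInput(species, pH, cfg["pKa_acid"], cfg["pKa_base"],
                           cfg["tautomers"])
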