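"""Solid-solution thermodynamics.

Per-molecule lattice energy of a doped supercell relative to gas-phase
references,

    E_latt = (E_cell - N_h * E_h - N_g * E_g) / N_cell,

ideal configurational entropy of mixing,

    dS_mix = -R (x_h ln x_h + x_g ln x_g),

a cubic trendline for the vibrational free-energy contribution F_vib(x) at
temperature T (relative to 0 K), total free energy

    G(x) = E_latt(x) + F_vib(x) - T * dS_mix(x),

the linear physical-mixture reference line, and the stability verdict of a
solid-solution curve against that line with an accessibility threshold
(default 2RT — a solid solution within 2RT of the most stable physical
mixture is treated as kinetically accessible under fast crystallization).

Units: energies in kJ/mol of molecules; entropy in J mol^-1 K^-1 and
converted to kJ at the free-energy assembly step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np
import pandas as pd

from .errors import ArgumentError, ConsistencyError
from .solid_solution import Composition

R_GAS = 8.314  # J mol^-1 K^-1
KCAL_TO_KJ = 4.184


@dataclass(frozen=True)
class EnergyAccounting:
    """Supercell electronic energy plus gas-phase references and counts."""

    E_cell: float  # kJ/mol of supercell
    E_h_ref: float  # kJ/mol per host molecule
    E_g_ref: float  # kJ/mol per guest molecule
    N_cell: int
    N_h: int
    N_g: int


def lattice_energy_ss(acct: EnergyAccounting) -> float:
    """Per-molecule solid-solution lattice energy (kJ/mol)."""
    if acct.N_cell < 1:
        raise ArgumentError("N_cell must be >= 1")
    if acct.N_h + acct.N_g != acct.N_cell:
        raise ConsistencyError("N_h + N_g must equal N_cell")
    return (acct.E_cell - acct.N_h * acct.E_h_ref
            - acct.N_g * acct.E_g_ref) / acct.N_cell


def mixing_entropy(comp: Composition | float) -> float:
    """Ideal mixing entropy, J mol^-1 K^-1, with the 0*ln0 = 0 convention."""
    x_g = comp.x_g if isinstance(comp, Composition) else float(comp)
    if not 0.0 <= x_g <= 1.0:
        raise ArgumentError("x_g must lie in [0, 1]")
    s = 0.0
    for x in (x_g, 1.0 - x_g):
        if x > 0.0:
            s -= x * math.log(x)
    return R_GAS * s


def vib_trendline(samples) -> np.poly1d:
    """Least-squares cubic through (x_g, F_vib) samples.

    Mirrors the common practice of fitting vibrational free energies computed
    at a few compositions (x in {0, 0.25, 0.5, 0.75, 1}) with a degree-3
    polynomial so the contribution can be evaluated on the whole range.
    """
    pts = [(float(x), float(f)) for x, f in samples]
    xs = np.array([p[0] for p in pts])
    fs = np.array([p[1] for p in pts])
    if len(np.unique(xs)) < 4:
        raise ArgumentError("cubic trendline needs >= 4 distinct x values")
    coeffs = np.polyfit(xs, fs, 3)
    return np.poly1d(coeffs)


@dataclass
class FreeEnergyCurve:
    """G(x) = E_latt + F_vib - T*dS_mix on a composition grid."""

    x_g: np.ndarray
    e_latt: np.ndarray  # kJ/mol per molecule
    f_vib: np.ndarray  # kJ/mol per molecule
    s_mix: np.ndarray  # J mol^-1 K^-1
    T: float  # K

    @property
    def g(self) -> np.ndarray:
        return self.e_latt + self.f_vib - self.T * self.s_mix * 1e-3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_g": self.x_g, "E_latt": self.e_latt, "F_vib": self.f_vib,
            "S_mix": self.s_mix, "G": self.g,
        })


def free_energy_curve(lattice_energies, trendline=None,
                      T: float = 300.0) -> FreeEnergyCurve:
    """Assemble the total free-energy curve from per-composition energies.

    ``lattice_energies``: sequence of (x_g, E_latt per molecule kJ/mol),
    covering at least two compositions including x_g = 0.
    ``trendline``: callable F_vib(x) in kJ/mol (e.g. from
    :func:`vib_trendline`); None means no vibrational term.
    """
    if T <= 0:
        raise ArgumentError("temperature must be > 0")
    pts = sorted((float(x), float(e)) for x, e in lattice_energies)
    if len(pts) < 2 or min(x for x, _ in pts) > 0.0:
        raise ArgumentError("need >= 2 compositions including x_g = 0")
    xs = np.array([p[0] for p in pts])
    es = np.array([p[1] for p in pts])
    fv = np.array([float(trendline(x)) if trendline is not None else 0.0
                   for x in xs])
    sm = np.array([mixing_entropy(x) for x in xs])
    return FreeEnergyCurve(xs, es, fv, sm, T)


# ---------------------------------------------------------------------------
# Physical mixture and stability


@dataclass(frozen=True)
class MixtureLine:
    """Linear free-energy interpolation between the pure end members."""

    g_host_pure: float  # kJ/mol at x = 0 (most stable pure host polymorph)
    g_guest_pure: float  # kJ/mol at x = 1 (most stable pure guest solid)

    def __call__(self, x_g: float) -> float:
        return physical_mixture(self, x_g)


def physical_mixture(line: MixtureLine, x_g: float) -> float:
    """Composition-weighted combination of the pure components' energies."""
    if not 0.0 <= x_g <= 1.0:
        raise ArgumentError("x_g must lie in [0, 1]")
    return (1.0 - x_g) * line.g_host_pure + x_g * line.g_guest_pure


STABLE = "stable"
METASTABLE = "metastable_accessible"
INACCESSIBLE = "inaccessible"


@dataclass(frozen=True)
class StabilityVerdict:
    x_g: float
    margin: float  # G(solid solution) - G(physical mixture), kJ/mol
    threshold: float  # accessibility bound, kJ/mol
    verdict: str
    below_polymorph_gap: bool | None = None


def accessibility_threshold(T: float = 300.0) -> float:
    """2RT in kJ/mol (≈ 4.99 at 300 K)."""
    return 2.0 * R_GAS * T * 1e-3


def load_energy_table(path, units: str = "kJ/mol") -> list[tuple[float, float]]:
    """Read a per-composition energy table (CSV or JSON records).

    Expected columns: ``x_g, E_cell, E_h_ref, E_g_ref, N_cell, N_h, N_g``
    (one supercell per row).  Energies declared in kcal/mol are converted
    to kJ/mol at parse time.  Returns (x_g, E_latt per molecule) pairs.
    """
    path = str(path)
    if path.endswith(".json"):
        df = pd.read_json(path)
    else:
        df = pd.read_csv(path)
    required = {"x_g", "E_cell", "E_h_ref", "E_g_ref", "N_cell", "N_h",
                "N_g"}
    missing = required - set(df.columns)
    if missing:
        raise ArgumentError(f"energy table missing columns {sorted(missing)}")
    factor = {"kJ/mol": 1.0, "kcal/mol": KCAL_TO_KJ}.get(units)
    if factor is None:
        raise ArgumentError(f"unknown energy units {units!r}")
    out = []
    for row in df.itertuples(index=False):
        acct = EnergyAccounting(row.E_cell * factor, row.E_h_ref * factor,
                                row.E_g_ref * factor, int(row.N_cell),
                                int(row.N_h), int(row.N_g))
        out.append((float(row.x_g), lattice_energy_ss(acct)))
    return out


def classify_stability(curve: FreeEnergyCurve, line: MixtureLine,
                       threshold: float | None = None,
                       polymorph_gap: float | None = None
                       ) -> list[StabilityVerdict]:
    """Classify each composition of the curve against the mixture line.

    margin <= 0 -> stable; 0 < margin <= threshold -> metastable but
    kinetically accessible; margin > threshold -> inaccessible.  When a
    host polymorph free-energy gap is supplied (energy of the metastable
    polymorph above the stable one), each verdict also reports whether the
    solid-solution excess drops below that gap.
    """
    if threshold is None:
        threshold = accessibility_threshold(curve.T)
    out = []
    for x, g in zip(curve.x_g, curve.g):
        margin = g - physical_mixture(line, float(x))
        if margin <= 0:
            v = STABLE
        elif margin <= threshold:
            v = METASTABLE
        else:
            v = INACCESSIBLE
        below = None if polymorph_gap is None else bool(margin < polymorph_gap)
        out.append(StabilityVerdict(float(x), float(margin), threshold, v,
                                    below))
    return out
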