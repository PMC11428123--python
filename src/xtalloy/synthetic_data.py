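"""Synthetic inputs: toy crystals, purine templates, interaction-energy
fixtures and a pairwise stand-in energy provider.

The toy "beta-like" motif emulates the packing of the monoclinic guanine
polymorph found in biogenic reflectors: planar molecules π-stacked along a
short *a* axis (≈3.6 Å gap), strong H-bonded chains along *b*, and weaker
secondary H-bonds linking dimers diagonally in the *bc* plane.  Fixture
energy tables are *qualitative*: they encode documented orderings (vacuum
3H-bond > 2H-bond > π-stack; water strengthens the hydrophobic π-stack and
weakens H-bonds; a nonpolar toluene-like solvent drives the π-stack
ΔG_cryst negative; guests selectively weaken the H-bond chain), never
digitized figure values.  Well depths sit at 2-25 kJ/mol so that RT at
300 K is a meaningful fraction of the interaction energies.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .crystal_model import (
    CrystalStructure,
    Molecule,
    MoleculeTemplate,
    UnitCell,
    expand_asymmetric,
)
from .errors import ArgumentError, ConfigError, GeometryError
from .interactions import (
    DEFAULT_CUTOFF,
    InteractionTable,
    assemble_dg_cryst,
    assign_geometric_labels,
    classify_unique,
    enumerate_neighbors,
)
from .solid_solution import SolidSolutionSupercell
from .thermo import EnergyAccounting

# ---------------------------------------------------------------------------
# Molecular templates


def toy_template(name: str = "toy-host", center_element: str = "C"
                 ) -> MoleculeTemplate:
    """Planar 5-atom cross in the molecular y-z plane (π plane ⊥ x)."""
    coords = np.array([
        [0.0, 0.0, 0.0],
        [0.0, 1.4, 0.0],
        [0.0, -1.4, 0.0],
        [0.0, 0.0, 1.4],
        [0.0, 0.0, -1.4],
    ])
    elements = (center_element, "N", "N", "O", "O")
    return MoleculeTemplate(name, "toy", elements, coords,
                            scaffold_atoms=(0, 1, 2, 3, 4))


def _purine_ring() -> tuple[np.ndarray, dict[str, int]]:
    """Idealized planar purine scaffold: fused 6- and 5-membered rings.

    Regular-polygon geometry with 1.39 Å bonds; not an experimental
    geometry, but shared exactly across the purine templates so scaffold
    superposition is well-conditioned.
    """
    s = 1.39
    hexagon = {}
    names6 = ["C4", "C5", "C6", "N1", "C2", "N3"]
    pts = []
    for i, nm in enumerate(names6):
        ang = math.radians(60.0 * i)
        pts.append([s * math.cos(ang), s * math.sin(ang), 0.0])
        hexagon[nm] = i
    pts = np.array(pts)
    # pentagon fused on the C4-C5 edge, on the opposite side of the hexagon
    p4, p5 = pts[hexagon["C4"]], pts[hexagon["C5"]]
    mid = (p4 + p5) / 2
    edge = p5 - p4
    peri = np.array([edge[1], -edge[0], 0.0])
    peri /= np.linalg.norm(peri)
    if np.dot(peri, mid) < 0:
        peri = -peri
    r5 = s / (2 * math.sin(math.pi / 5))
    apo = r5 * math.cos(math.pi / 5)
    c5 = mid + peri * apo
    a4 = math.atan2(p4[1] - c5[1], p4[0] - c5[0])
    a5 = math.atan2(p5[1] - c5[1], p5[0] - c5[0])
    # step around the pentagon away from p4: p5, then N7, C8, N9
    step = 2 * math.pi / 5
    diff = (a5 - a4 + math.pi) % (2 * math.pi) - math.pi
    sign = 1.0 if diff > 0 else -1.0
    ring5 = []
    for k in (1, 2, 3):
        ang = a5 + sign * step * k
        ring5.append([c5[0] + r5 * math.cos(ang), c5[1] + r5 * math.sin(ang),
                      0.0])
    coords = np.vstack([pts, np.array(ring5)])
    index = dict(hexagon)
    index.update({"N7": 6, "C8": 7, "N9": 8})
    return coords, index


def _exocyclic(coords: np.ndarray, idx: int, bond: float = 1.23) -> np.ndarray:
    """Place a substituent radially outward from the ring centroid."""
    center = coords[:9].mean(axis=0)
    v = coords[idx] - center
    v /= np.linalg.norm(v)
    return coords[idx] + v * bond


def purine_template(name: str, tautomer: str | None = None) -> MoleculeTemplate:
    """Idealized guanine / hypoxanthine / xanthine template.

    Atom order: the nine ring heavy atoms (C4 C5 C6 N1 C2 N3 N7 C8 N9),
    then the keto oxygen O6, then species-specific substituents; the
    scaffold is the ring plus O6, identical across the family.
    """
    ring, index = _purine_ring()
    elements = ["C", "C", "C", "N", "C", "N", "N", "C", "N"]
    coords = [ring[i] for i in range(9)]
    coords.append(_exocyclic(ring, index["C6"]))  # O6
    elements.append("O")
    scaffold = tuple(range(10))
    if name == "guanine":
        tautomer = tautomer or "keto-N7H"
        coords.append(_exocyclic(ring, index["C2"], 1.34))  # amino N2
        elements.append("N")
    elif name == "hypoxanthine":
        tautomer = tautomer or "keto-N7H"
    elif name == "xanthine":
        tautomer = tautomer or "keto-enol-N7H"
        coords.append(_exocyclic(ring, index["C2"], 1.23))  # O2
        elements.append("O")
    else:
        raise ArgumentError(f"unknown purine {name!r}")
    return MoleculeTemplate(name, tautomer, tuple(elements),
                            np.array(coords), scaffold)


# ---------------------------------------------------------------------------
# Toy crystal structures


def make_toy_structure(
    motif: str = "beta",
    a: float = 3.6,
    b: float = 6.0,
    c: float = 7.0,
    beta: float = 96.0,
    cubic_a: float = 3.5,
) -> CrystalStructure:
    """Deterministic toy crystal with a guanine-like contact graph.

    motifs:
      * ``beta``  — Z=2 monoclinic cell; π-stacking along *a*, chain
        contacts along *b*, four diagonal dimer contacts in the *bc* plane
        (the second molecule is generated by a centering translation so the
        two sublattices are symmetry-equivalent).
      * ``beta4`` — same motif with a doubled *c* axis, Z=4 (the packaged
        synthetic stand-in for the published β-guanine cell content).
      * ``cubic`` — Z=1 single-atom molecule on a simple cubic lattice.
    """
    tmpl = toy_template()
    if motif == "cubic":
        cell = UnitCell(cubic_a, cubic_a, cubic_a)
        one = MoleculeTemplate("toy-host", "toy", ("C",),
                               np.zeros((1, 3)), (0,))
        mol = _place(cell, one, (0.25, 0.25, 0.25))
        struct = CrystalStructure(cell, [mol], ["x,y,z"], 1, "toy-cubic")
    elif motif == "beta":
        cell = UnitCell(a, b, c, 90.0, beta, 90.0)
        mol = _place(cell, tmpl, (0.25, 0.25, 0.25))
        struct = expand_asymmetric(cell, [mol],
                                   ["x,y,z", "x,y+1/2,z+1/2"],
                                   name="toy-beta")
    elif motif == "beta4":
        cell = UnitCell(a, b, 2 * c, 90.0, beta, 90.0)
        mol = _place(cell, tmpl, (0.25, 0.25, 0.125))
        struct = expand_asymmetric(
            cell, [mol],
            ["x,y,z", "x,y+1/2,z+1/4", "x,y,z+1/2", "x,y+1/2,z+3/4"],
            name="toy-beta4")
    else:
        raise ArgumentError(f"unknown motif {motif!r}")
    _check_no_overlap(struct)
    return struct


def _place(cell: UnitCell, tmpl: MoleculeTemplate,
           centroid_frac) -> Molecule:
    inv = np.linalg.inv(cell.matrix)
    frac = tmpl.coords @ inv.T
    frac = frac - frac.mean(axis=0) + np.asarray(centroid_frac, float)
    return Molecule("host", tmpl.elements, frac, tmpl)


def _check_no_overlap(struct: CrystalStructure, min_gap: float = 1.5) -> None:
    contacts = enumerate_neighbors(struct, cutoff=min_gap)
    if contacts:
        worst = min(c.min_distance for c in contacts)
        raise GeometryError(f"motif places molecules {worst:.2f} Å apart")


# ---------------------------------------------------------------------------
# Solvent profiles and guest perturbations


@dataclass(frozen=True)
class SolventProfile:
    """Per-interaction-label ΔG_desolv offsets (kJ/mol, half-bond)."""

    label: str
    offsets: dict[str, float] = field(hash=False)

    def offset_for(self, label: str) -> float:
        if label in self.offsets:
            return self.offsets[label]
        if label.startswith("other") and "other" in self.offsets:
            return self.offsets["other"]
        raise ConfigError(f"solvent profile {self.label!r} has no offset for "
                          f"interaction label {label!r}")


VACUUM = SolventProfile("vacuum", {"π-stack": 0.0, "3H-bond": 0.0,
                                   "2H-bond": 0.0, "other": 0.0})
# water: desolvating the hydrophobic stacking contact is favorable (negative
# cost -> π-stack strengthened); stripping water from H-bond donors/acceptors
# is expensive -> H-bond chain strongly weakened.
WATER = SolventProfile("water", {"π-stack": -8.0, "3H-bond": 5.5,
                                 "2H-bond": 3.5, "other": 2.0})
# toluene-like nonpolar solvent: aromatic faces are well solvated (high
# desolvation cost drives π-stack ΔG_cryst negative); H-bonds nearly as in
# the solid state.
TOLUENE = SolventProfile("toluene", {"π-stack": 9.0, "3H-bond": 1.5,
                                     "2H-bond": 1.0, "other": 1.0})
SOLVENTS = {p.label: p for p in (VACUUM, WATER, TOLUENE)}


@dataclass(frozen=True)
class GuestPerturbation:
    """Multiplicative (then additive) modifiers of ΔG_vacuum per label."""

    guest: str
    scale: dict[str, float] = field(hash=False)
    shift: dict[str, float] = field(default_factory=dict, hash=False)

    def apply(self, label: str, value: float) -> float:
        key = label if label in self.scale else (
            "other" if label.startswith("other") else label)
        return value * self.scale.get(key, 1.0) + self.shift.get(key, 0.0)


IDENTITY_GUEST = GuestPerturbation("none", {})
# hpx-like: interrupts the triple-H-bond chain, mildly weakens the dimer
# H-bond, leaves stacking untouched.
HPX_LIKE = GuestPerturbation("hpx", {"3H-bond": 0.5, "2H-bond": 0.85,
                                     "π-stack": 1.0, "other": 0.9})
# xan-like: stronger in-plane disruption, slightly bulkier stack.
XAN_LIKE = GuestPerturbation("xan", {"3H-bond": 0.45, "2H-bond": 0.70,
                                     "π-stack": 1.05, "other": 0.85})
GUESTS = {"none": IDENTITY_GUEST, "hpx": HPX_LIKE, "xan": XAN_LIKE}

# host vacuum well depths per interaction label (kJ/mol, half-bond)
HOST_WELLS = {"π-stack": 5.0, "3H-bond": 9.5, "2H-bond": 9.0, "other": 2.5}

# per-guest lattice-energy penalties for the pairwise stand-in model
# (kJ/mol per participating molecule); the xan-like set is twice the
# hpx-like set so the lattice-energy slope ratio is 2.
FIXTURE_PENALTIES = {
    "hpx": {"3H-bond": 3.0, "2H-bond": 1.0, "π-stack": 0.5, "other": 0.5},
    "xan": {"3H-bond": 6.0, "2H-bond": 2.0, "π-stack": 1.0, "other": 1.0},
}


def guest_toy_template(name: str = "hpx") -> MoleculeTemplate:
    """Toy guest with the host scaffold geometry (exact superposition)."""
    return toy_template(name, center_element="N")


def default_energy_model(noise_scale: float = 0.0,
                         seed: int = 0) -> PairwiseEnergyModel:
    """Pairwise model with the fixture wells and guest penalties."""
    return PairwiseEnergyModel(penalties={k: dict(v) for k, v
                                          in FIXTURE_PENALTIES.items()},
                               noise_scale=noise_scale, seed=seed)


def _well_for(label: str, wells: dict[str, float]) -> float:
    if label in wells:
        return wells[label]
    if label.startswith("other") and "other" in wells:
        return wells["other"]
    raise ConfigError(f"no well depth for interaction label {label!r}")


def make_interaction_table(
    structure: CrystalStructure,
    solvent: SolventProfile = VACUUM,
    guest: GuestPerturbation | None = None,
    wells: dict[str, float] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> InteractionTable:
    """Classified interaction table with fixture energies attached.

    ΔG_vacuum per type from the host well depths (guest perturbation applied
    last), ΔG_desolv from the solvent profile, ΔG_cryst by identity.
    """
    wells = wells or HOST_WELLS
    guest = guest or IDENTITY_GUEST
    contacts = enumerate_neighbors(structure, cutoff)
    table = classify_unique(contacts, structure)
    table = assign_geometric_labels(structure, table)
    vac: dict[int, float] = {}
    des: dict[int, float] = {}
    for t in table.types:
        vac[t.type_id] = guest.apply(t.label, _well_for(t.label, wells))
        des[t.type_id] = solvent.offset_for(t.label)
    return assemble_dg_cryst(table, vac, des, solvent=solvent.label)


# ---------------------------------------------------------------------------
# Pairwise stand-in energy provider


@dataclass
class PairwiseEnergyModel:
    """Additive pair-well model standing in for electronic supercell energies.

    Dimer energy of a contact with label L between species s1, s2:
    ``-(wells[L] - penalty[s1][L] - penalty[s2][L])`` — each guest
    participant weakens the interaction by its per-label penalty.  The
    supercell energy is the half-bond-consistent sum over directed contacts,
    which is extensive and exactly linear in the guest count.
    """

    wells: dict[str, float] = field(default_factory=lambda: dict(HOST_WELLS))
    penalties: dict[str, dict[str, float]] = field(default_factory=dict)
    ref_energies: dict[str, float] = field(default_factory=dict)
    noise_scale: float = 0.0
    seed: int = 0
    cutoff: float = DEFAULT_CUTOFF
    _cache: dict = field(default_factory=dict, repr=False)

    def penalty(self, species: str, label: str) -> float:
        per = self.penalties.get(species)
        if per is None:
            if species in ("host", "toy-host", "guanine"):
                return 0.0
            raise ConfigError(f"no penalty parameters for species {species!r}")
        key = label if label in per else (
            "other" if label.startswith("other") else label)
        return per.get(key, 0.0)

    def _labeled_contacts(self, base: CrystalStructure):
        cell = base.cell
        key = (base.name, base.Z, round(cell.a, 6), round(cell.b, 6),
               round(cell.c, 6), round(cell.beta, 6))
        if key not in self._cache:
            contacts = enumerate_neighbors(base, self.cutoff)
            m = cell.matrix
            axes = m / np.linalg.norm(m, axis=0)
            labeled = []
            for cpair in contacts:
                v = cell.to_cart(np.array(cpair.frac_vector))
                u = v / np.linalg.norm(v)
                pa, pb = abs(u @ axes[:, 0]), abs(u @ axes[:, 1])
                if pa > 0.8:
                    lab = "π-stack"
                elif pb > 0.8:
                    lab = "3H-bond"
                elif pa < 0.4:
                    lab = "2H-bond"
                else:
                    lab = "other"
                labeled.append((cpair.central, cpair.neighbor, lab))
            self._cache[key] = labeled
        return self._cache[key]


def supercell_energy(model: PairwiseEnergyModel,
                     ss: SolidSolutionSupercell) -> EnergyAccounting:
    """Electronic-energy stand-in for a doped supercell.

    Contacts are evaluated on the host contact topology (guest scaffolds are
    superposed onto the host sites, so the contact graph is unchanged).
    """
    labeled = model._labeled_contacts(ss.base)
    host = ss.host_species
    total = 0.0
    for i, j, lab in labeled:
        w = _well_for(lab, model.wells)
        w -= model.penalty(ss.occupants[i], lab)
        w -= model.penalty(ss.occupants[j], lab)
        total += w
    e_cell = -0.5 * total
    if model.noise_scale > 0:
        tag = zlib.crc32("".join(ss.occupants).encode())
        rng = np.random.default_rng((model.seed, tag))
        e_cell += float(rng.normal(0.0, model.noise_scale))
    e_h = model.ref_energies.get(host, 0.0)
    guests = [s for s in ss.occupants if s != host]
    e_g = model.ref_energies.get(guests[0], 0.0) if guests else 0.0
    return EnergyAccounting(e_cell, e_h, e_g, ss.N_cell, ss.N_h, ss.N_g)


def per_guest_penalty(model: PairwiseEnergyModel, species: str,
                      structure: CrystalStructure) -> float:
    """Injected per-guest lattice-energy increment: Σ_contacts penalty(label).

    The closed-form slope of E_latt(x)·N against N_g for this model.
    """
    labeled = model._labeled_contacts(structure)
    per_mol: dict[int, float] = {}
    for i, j, lab in labeled:
        per_mol[i] = per_mol.get(i, 0.0) + model.penalty(species, lab)
    # every site is equivalent in the toy motifs; average for safety
    return float(np.mean(list(per_mol.values())))


def beta_guanine_fixture_path():
    """Path of the packaged synthetic β-guanine-like CIF (Z = 4).

    A synthetic stand-in whose contact topology — not geometry — matches
    the published polymorph; see the file header.
    """
    from importlib.resources import files
    return files("xtalloy").joinpath("data/beta_guanine_synthetic.cif")


def synthetic_vib_samples(xs=(0.0, 0.25, 0.5, 0.75, 1.0)):
    """Fixture vibrational free-energy samples F_vib(x) at 300 K (kJ/mol)."""
    return [(x, 0.8 - 0.3 * x + 0.15 * x * x + 0.05 * x ** 3) for x in xs]
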