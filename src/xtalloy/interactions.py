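"""Neighbor contacts, symmetry-unique interaction types, and ΔG_cryst tables.

A molecule B is a neighbor of A iff the minimum atom-atom distance between
them over all periodic images is within the cutoff (3.8 Å by default, the
solvation-partitioning convention).  Two contacts belong to the same
interaction type iff a symmetry operation of the structure (combined with
A<->B exchange) maps one molecular pair onto the other.

Sign convention: ΔG_cryst = ΔG_vacuum - ΔG_desolv is *positive when
crystallization of the interaction is favorable* — a larger ΔG_cryst means
faster growth along that contact.  (The upstream solvation-partitioning
literature uses the opposite sign internally.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .crystal_model import CrystalStructure, parse_symop
from .errors import (
    ArgumentError,
    ClassificationError,
    IncompleteTableError,
)

DEFAULT_CUTOFF = 3.8  # Å


@dataclass(frozen=True)
class NeighborContact:
    """Directed contact: central molecule -> neighbor molecule + cell offset."""

    central: int
    neighbor: int
    offset: tuple[int, int, int]
    min_distance: float  # Å
    frac_vector: tuple[float, float, float]  # centroid-to-centroid, fractional

    def reverse(self) -> "NeighborContact":
        return NeighborContact(
            self.neighbor, self.central,
            tuple(-o for o in self.offset), self.min_distance,
            tuple(-v for v in self.frac_vector))

    def key(self) -> tuple:
        return (self.central, self.neighbor, self.offset)


def enumerate_neighbors(structure: CrystalStructure,
                        cutoff: float = DEFAULT_CUTOFF
                        ) -> list[NeighborContact]:
    """All directed neighbor contacts within ``cutoff`` (periodic images).

    The image search range expands automatically when the cutoff (plus the
    molecular extents) exceeds the cell heights, so small cells are handled
    without error.
    """
    if cutoff <= 0:
        raise ArgumentError("cutoff must be > 0")
    if structure.Z < 1:
        raise ArgumentError("structure has no molecules")
    cell = structure.cell
    carts = [m.cart(cell) for m in structure.molecules]
    centroids_f = [m.centroid for m in structure.molecules]
    # molecular radius: max distance of an atom from the centroid
    radii = [float(np.linalg.norm(c - c.mean(axis=0), axis=1).max())
             for c in carts]
    rmax = max(radii)
    reach = cutoff + 2 * rmax
    heights = cell.heights()
    ranges = [int(np.ceil(reach / h)) for h in heights]

    contacts: list[NeighborContact] = []
    for i in range(structure.Z):
        for j in range(structure.Z):
            for di in range(-ranges[0], ranges[0] + 1):
                for dj in range(-ranges[1], ranges[1] + 1):
                    for dk in range(-ranges[2], ranges[2] + 1):
                        off = (di, dj, dk)
                        if i == j and off == (0, 0, 0):
                            continue
                        shift = cell.to_cart(np.array(off, float))
                        d = cdist(carts[i], carts[j] + shift).min()
                        if d <= cutoff:
                            fvec = (centroids_f[j] + np.array(off, float)
                                    - centroids_f[i])
                            contacts.append(NeighborContact(
                                i, j, off, float(d),
                                tuple(float(x) for x in fvec)))
    return contacts


# ---------------------------------------------------------------------------
# Symmetry-unique classification


@dataclass
class InteractionType:
    """A symmetry-unique neighbor interaction with its energies (kJ/mol).

    Energies follow the half-bond convention: each value is the per-molecule
    share (half) of the full dimer interaction energy.
    """

    type_id: int
    label: str = "other"
    multiplicity: float = 0.0  # contacts per molecule
    dg_vacuum: float | None = None
    dg_desolv: float | None = None
    dg_cryst: float | None = None
    example: NeighborContact | None = None


@dataclass
class InteractionTable:
    structure_id: str
    types: list[InteractionType]
    solvent: str = "vacuum"
    contact_type: dict[tuple, int] = field(default_factory=dict)
    contacts: list[NeighborContact] = field(default_factory=list)

    def type_by_id(self, type_id: int) -> InteractionType:
        for t in self.types:
            if t.type_id == type_id:
                return t
        raise KeyError(type_id)

    def dg_by_label(self) -> dict[str, float]:
        return {t.label: t.dg_cryst for t in self.types}

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "type_id": t.type_id, "label": t.label,
            "multiplicity": t.multiplicity, "dg_vacuum": t.dg_vacuum,
            "dg_desolv": t.dg_desolv, "dg_cryst": t.dg_cryst,
            "solvent": self.solvent,
        } for t in self.types])

    def to_json(self, path=None) -> str:
        payload = {
            "structure_id": self.structure_id,
            "solvent": self.solvent,
            "types": [{
                "type_id": t.type_id, "label": t.label,
                "multiplicity": t.multiplicity, "dg_vacuum": t.dg_vacuum,
                "dg_desolv": t.dg_desolv, "dg_cryst": t.dg_cryst,
            } for t in self.types],
            "contacts": [{
                "central": c.central, "neighbor": c.neighbor,
                "offset": list(c.offset), "min_distance": c.min_distance,
                "frac_vector": list(c.frac_vector),
                "type_id": self.contact_type.get(c.key()),
            } for c in self.contacts],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "InteractionTable":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        types = [InteractionType(t["type_id"], t["label"], t["multiplicity"],
                                 t["dg_vacuum"], t["dg_desolv"], t["dg_cryst"])
                 for t in payload["types"]]
        contacts = []
        ctype = {}
        for c in payload.get("contacts", []):
            nc = NeighborContact(c["central"], c["neighbor"],
                                 tuple(c["offset"]), c["min_distance"],
                                 tuple(c["frac_vector"]))
            contacts.append(nc)
            if c.get("type_id") is not None:
                ctype[nc.key()] = c["type_id"]
        return cls(payload["structure_id"], types, payload["solvent"],
                   ctype, contacts)


def _symop_molecule_maps(structure: CrystalStructure, tol: float = 0.05
                         ) -> list[tuple[np.ndarray, list[tuple[int, np.ndarray]]]]:
    """For each symmetry op: rotation matrix + per-molecule image (index, shift)."""
    cents = [m.centroid for m in structure.molecules]
    maps = []
    for triplet in structure.symmetry_xyz:
        rot, tran = parse_symop(triplet)
        images: list[tuple[int, np.ndarray]] = []
        ok = True
        for c in cents:
            c2 = rot @ c + tran
            hit = None
            for j, cj in enumerate(cents):
                d = c2 - cj
                s = np.round(d)
                if np.all(np.abs(d - s) < tol):
                    hit = (j, s)
                    break
            if hit is None:
                ok = False
                break
            images.append(hit)
        if ok:
            maps.append((rot, images))
    return maps


def classify_unique(contacts: list[NeighborContact],
                    structure: CrystalStructure,
                    tol: float = 0.05) -> InteractionTable:
    """Partition contacts into symmetry-unique interaction types.

    Contacts form orbits under the structure's symmetry operations composed
    with central<->neighbor exchange; each orbit is one interaction type.
    Multiplicity = directed contacts of the type per molecule.
    """
    if not contacts:
        raise ArgumentError("no contacts to classify")
    keys = {c.key(): n for n, c in enumerate(contacts)}
    maps = _symop_molecule_maps(structure, tol)

    parent = list(range(len(contacts)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    def locate(central: int, neighbor: int, off: np.ndarray) -> int | None:
        key = (central, neighbor, tuple(int(round(o)) for o in off))
        return keys.get(key)

    for n, c in enumerate(contacts):
        rev = locate(c.neighbor, c.central, -np.array(c.offset))
        if rev is None:
            raise ClassificationError(
                f"contact {c.key()} has no reverse partner")
        union(n, rev)
        for rot, images in maps:
            i2, s_i = images[c.central]
            j2, s_j = images[c.neighbor]
            off2 = rot @ np.array(c.offset, float) + s_j - s_i
            img = locate(i2, j2, off2)
            if img is not None:
                union(n, img)

    groups: dict[int, list[int]] = {}
    for n in range(len(contacts)):
        groups.setdefault(find(n), []).append(n)

    types = []
    contact_type: dict[tuple, int] = {}
    for tid, (_, members) in enumerate(sorted(
            groups.items(),
            key=lambda kv: min(contacts[m].min_distance for m in kv[1]))):
        mult = len(members) / structure.Z
        rep = min(members, key=lambda m: contacts[m].key())
        types.append(InteractionType(tid, "other", mult,
                                     example=contacts[rep]))
        for m in members:
            contact_type[contacts[m].key()] = tid
    return InteractionTable(structure.name, types, "vacuum",
                            contact_type, list(contacts))


def assign_geometric_labels(structure: CrystalStructure,
                            table: InteractionTable) -> InteractionTable:
    """Heuristic chemistry labels from contact geometry.

    Contacts whose centroid-centroid vector points dominantly along *a* are
    labeled 'π-stack' (the stacking axis of the guanine-like motif), those
    along *b* '3H-bond' (the triple-H-bond chain), other in-plane (bc)
    contacts '2H-bond', and the remainder 'other-N'.
    """
    m = structure.cell.matrix
    axes = m / np.linalg.norm(m, axis=0)
    other = 0
    for t in table.types:
        if t.example is None:
            continue
        v = structure.cell.to_cart(np.array(t.example.frac_vector))
        u = v / np.linalg.norm(v)
        pa, pb = abs(u @ axes[:, 0]), abs(u @ axes[:, 1])
        if pa > 0.8:
            t.label = "π-stack"
        elif pb > 0.8:
            t.label = "3H-bond"
        elif pa < 0.4:
            t.label = "2H-bond"
        else:
            other += 1
            t.label = f"other-{other}"
    return table


# ---------------------------------------------------------------------------
# Energies


def half_bond(total_dimer_energy: float) -> float:
    """Per-molecule share of a dimer interaction energy (half bond)."""
    return total_dimer_energy / 2.0


def assemble_dg_cryst(table: InteractionTable,
                      vacuum: dict[int, float],
                      desolvation: dict[int, float] | None = None,
                      solvent: str = "vacuum") -> InteractionTable:
    """Attach ΔG_vacuum / ΔG_desolv per type and compute ΔG_cryst.

    ``vacuum`` and ``desolvation`` map type_id -> energy (kJ/mol, half-bond
    convention).  ``desolvation=None`` means vacuum growth (ΔG_desolv = 0).
    """
    new_types = []
    for t in table.types:
        if t.type_id not in vacuum:
            raise IncompleteTableError(f"missing vacuum energy for type "
                                       f"{t.type_id} ({t.label})")
        dgv = float(vacuum[t.type_id])
        if desolvation is None:
            dgd = 0.0
        else:
            if t.type_id not in desolvation:
                raise IncompleteTableError(f"missing desolvation energy for "
                                           f"type {t.type_id} ({t.label})")
            dgd = float(desolvation[t.type_id])
        new_types.append(replace(t, dg_vacuum=dgv, dg_desolv=dgd,
                                 dg_cryst=dgv - dgd))
    return InteractionTable(table.structure_id, new_types, solvent,
                            dict(table.contact_type), list(table.contacts))
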