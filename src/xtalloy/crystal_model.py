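"""Crystal structures: unit cells, symmetry, supercells, d-spacings, CIF I/O.

Conventions
-----------
Coordinates are fractional internally; Cartesian coordinates appear only at
geometry operations.  The fractional->Cartesian conversion uses a fixed
column-basis matrix with the *a* axis along x and *b* in the x-y plane, so a
structure is fully determined by its cell parameters and fractional content.

A :class:`CrystalStructure` stores the complete unit-cell content as a list of
:class:`Molecule` instances (species label + per-atom fractional coordinates)
together with the symmetry operations (as xyz triplet strings) and the indices
of the molecules forming the asymmetric unit.  Structures read from CIF are
assembled from atom sites by covalent-distance bonding.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field


import gemmi
import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    ArgumentError,
    FormatError,
    GeometryError,
    UnsupportedFeatureError,
)

# Covalent radii (Å), Cordero et al. consensus values for the elements that
# occur in purine crystals; unknown elements fall back to 0.75 Å.
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
DEFAULT_RADIUS = 0.75
BOND_TOLERANCE = 1.15  # multiplier on the covalent-radii sum


# ---------------------------------------------------------------------------
# Unit cell


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ArgumentError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ArgumentError(f"cell angle {name} must be in (0, 180)")
        if self.volume <= 0:
            raise ArgumentError("cell parameters give non-positive volume")

    @property
    def matrix(self) -> np.ndarray:
        """Column-basis matrix M with cart = M @ frac (a along x, b in xy)."""
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(max(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg, 0.0))
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    @property
    def metric(self) -> np.ndarray:
        m = self.matrix
        return m.T @ m

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        v2 = 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        if v2 <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(v2)

    def to_cart(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.matrix.T

    def heights(self) -> np.ndarray:
        """Perpendicular distances between the three pairs of cell faces."""
        m = self.matrix
        vol = abs(np.linalg.det(m))
        h = np.empty(3)
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            h[i] = vol / np.linalg.norm(np.cross(m[:, j], m[:, k]))
        return h


@dataclass(frozen=True)
class MillerIndex:
    h: int
    k: int
    l: int

    def __post_init__(self) -> None:
        if self.h == self.k == self.l == 0:
            raise ArgumentError("Miller index (0,0,0) is undefined")

    def as_array(self) -> np.ndarray:
        return np.array([self.h, self.k, self.l], dtype=float)


def d_spacing(cell: UnitCell, hkl: MillerIndex | tuple[int, int, int]) -> float:
    """Interplanar spacing d(hkl) from the triclinic reciprocal metric."""
    if not isinstance(hkl, MillerIndex):
        hkl = MillerIndex(*hkl)
    g_star = np.linalg.inv(cell.metric)
    v = hkl.as_array()
    return float(1.0 / math.sqrt(v @ g_star @ v))


# ---------------------------------------------------------------------------
# Molecules


@dataclass(frozen=True)
class MoleculeTemplate:
    """Rigid molecular geometry in its own Cartesian frame (Å).

    ``scaffold_atoms`` indexes the atom subset shared across the purine
    family (ring heavy atoms plus mapped keto oxygens) used for rigid-body
    superposition during substitution.
    """

    name: str
    tautomer: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (n, 3) Cartesian Å
    scaffold_atoms: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if len(self.elements) < 1 or coords.shape != (len(self.elements), 3):
            raise ArgumentError("template needs >=1 atom with (n,3) coordinates")
        if any(i < 0 or i >= len(self.elements) for i in self.scaffold_atoms):
            raise ArgumentError("scaffold_atoms indices out of range")
        if len(self.elements) > 1:
            d = cdist(coords, coords)
            np.fill_diagonal(d, np.inf)
            if d.min() < 0.5:
                raise GeometryError("template atoms closer than 0.5 Å")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class Molecule:
    """A molecule placed in a crystal: species label + fractional atom coords."""

    species: str
    elements: tuple[str, ...]
    frac: np.ndarray  # (n, 3) fractional
    template: MoleculeTemplate | None = None

    def __post_init__(self) -> None:
        self.frac = np.asarray(self.frac, dtype=float)

    @property
    def centroid(self) -> np.ndarray:
        return self.frac.mean(axis=0)

    def cart(self, cell: UnitCell) -> np.ndarray:
        return cell.to_cart(self.frac)

    def shifted(self, shift: np.ndarray) -> "Molecule":
        return Molecule(self.species, self.elements, self.frac + shift,
                        self.template)


# ---------------------------------------------------------------------------
# Symmetry operations

def parse_symop(triplet: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse an xyz triplet ('x, y+1/2, z') into (rotation, translation)."""
    try:
        op = gemmi.Op(triplet)
    except Exception as exc:  # pragma: no cover - gemmi raises RuntimeError
        raise FormatError(f"bad symmetry triplet {triplet!r}: {exc}") from exc
    rot = np.array(op.rot, dtype=float) / op.DEN
    tran = np.array(op.tran, dtype=float) / op.DEN
    return rot, tran


def apply_symop(triplet: str, frac: np.ndarray) -> np.ndarray:
    rot, tran = parse_symop(triplet)
    return np.asarray(frac) @ rot.T + tran


# ---------------------------------------------------------------------------
# Crystal structure


@dataclass
class CrystalStructure:
    """Unit cell + symmetry + full unit-cell molecule content.

    ``molecules`` is the complete cell content (Z molecules); the first
    ``n_asym`` entries form the asymmetric unit, and expanding them with
    ``symmetry_xyz`` reproduces the full list (checked by
    :func:`expand_asymmetric`).
    """

    cell: UnitCell
    molecules: list[Molecule]
    symmetry_xyz: list[str] = field(default_factory=lambda: ["x,y,z"])
    n_asym: int | None = None
    name: str = "structure"

    def __post_init__(self) -> None:
        if self.n_asym is None:
            self.n_asym = len(self.molecules)
        if not any(_is_identity(s) for s in self.symmetry_xyz):
            raise ArgumentError("identity symmetry operation missing")

    @property
    def Z(self) -> int:
        return len(self.molecules)

    @property
    def asym_molecules(self) -> list[Molecule]:
        return self.molecules[: self.n_asym]

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(
            self.cell,
            [Molecule(m.species, m.elements, m.frac.copy(), m.template)
             for m in self.molecules],
            list(self.symmetry_xyz),
            self.n_asym,
            self.name,
        )


def _is_identity(triplet: str) -> bool:
    rot, tran = parse_symop(triplet)
    return np.allclose(rot, np.eye(3)) and np.allclose(tran % 1.0, 0.0)


def _wrap_molecule(mol: Molecule) -> Molecule:
    shift = -np.floor(mol.centroid)
    return mol.shifted(shift)


def expand_asymmetric(
    cell: UnitCell,
    asym: list[Molecule],
    symmetry_xyz: list[str],
    tol: float = 1e-3,
    name: str = "structure",
) -> CrystalStructure:
    """Apply all symmetry operations to the asymmetric unit and deduplicate.

    Molecules whose wrapped centroids coincide (within ``tol`` fractional)
    are considered symmetry duplicates.
    """
    out: list[Molecule] = []
    for mol in asym:
        out.append(_wrap_molecule(mol))
    seen_from = len(out)
    for triplet in symmetry_xyz:
        rot, tran = parse_symop(triplet)
        for mol in asym:
            frac = mol.frac @ rot.T + tran
            cand = _wrap_molecule(Molecule(mol.species, mol.elements, frac,
                                           mol.template))
            if not any(_same_site(cand, m, tol) for m in out):
                out.append(cand)
    del seen_from
    return CrystalStructure(cell, out, list(symmetry_xyz), len(asym), name)


def _same_site(m1: Molecule, m2: Molecule, tol: float) -> bool:
    d = m1.centroid - m2.centroid
    d -= np.round(d)
    return bool(np.all(np.abs(d) < tol))


# ---------------------------------------------------------------------------
# Supercell


def build_supercell(structure: CrystalStructure,
                    repeats: tuple[int, int, int]) -> CrystalStructure:
    """Replicate the unit cell ``repeats`` = (na, nb, nc) times along a, b, c.

    The result is expressed in the enlarged cell (P1): molecule ordering is
    cell-major — for each translation (i, j, k) in C-order, the Z parent
    molecules in their original order — which downstream site bookkeeping
    relies on.
    """
    na, nb, nc = repeats
    if min(na, nb, nc) < 1:
        raise ArgumentError("supercell repeats must be >= 1")
    cell = structure.cell
    new_cell = UnitCell(cell.a * na, cell.b * nb, cell.c * nc,
                        cell.alpha, cell.beta, cell.gamma)
    scale = np.array([na, nb, nc], dtype=float)
    mols: list[Molecule] = []
    for i in range(na):
        for j in range(nb):
            for k in range(nc):
                shift = np.array([i, j, k], dtype=float)
                for m in structure.molecules:
                    mols.append(Molecule(m.species, m.elements,
                                         (m.frac + shift) / scale, m.template))
    out = CrystalStructure(new_cell, mols, ["x,y,z"], len(mols),
                           f"{structure.name}_{na}x{nb}x{nc}")
    out.repeats = repeats  # type: ignore[attr-defined]
    out.parent_Z = structure.Z  # type: ignore[attr-defined]
    out.parent = structure  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# CIF input


def read_cif(path, bond_tolerance: float = BOND_TOLERANCE) -> CrystalStructure:
    """Read a CIF file and assemble molecules by covalent-distance bonding.

    Molecules are the connected components of the bond graph built over the
    symmetry-expanded atom sites (edges where the periodic minimum distance
    is below the covalent-radii sum times ``bond_tolerance``); components are
    unwrapped across cell boundaries so every molecule is geometrically whole.
    """
    try:
        doc = gemmi.cif.read(str(path))
    except Exception as exc:
        raise FormatError(f"CIF parse failure in {path}: {exc}") from exc
    block = doc.sole_block()

    def need(tag: str) -> float:
        val = block.find_value(tag)
        if val is None:
            raise FormatError(f"CIF missing required item {tag}")
        try:
            return float(gemmi.cif.as_number(val))
        except Exception as exc:
            raise FormatError(f"CIF item {tag} not numeric: {val!r}") from exc

    cell = UnitCell(need("_cell_length_a"), need("_cell_length_b"),
                    need("_cell_length_c"), need("_cell_angle_alpha"),
                    need("_cell_angle_beta"), need("_cell_angle_gamma"))

    sym: list[str] = []
    for tag in ("_symmetry_equiv_pos_as_xyz",
                "_space_group_symop_operation_xyz"):
        col = block.find_loop(tag)
        if col:
            sym = [gemmi.cif.as_string(v) for v in col]
            break
    if not sym:
        sym = ["x,y,z"]

    table = block.find("_atom_site_", ["label", "type_symbol",
                                      "fract_x", "fract_y", "fract_z"])
    occ_col = block.find_loop("_atom_site_occupancy")
    occs = [gemmi.cif.as_number(v) for v in occ_col] if occ_col else []
    if not table:
        # fall back: some files omit type_symbol
        table = block.find("_atom_site_", ["label", "fract_x", "fract_y",
                                           "fract_z"])
        if not table:
            raise FormatError("CIF missing _atom_site_ loop with fractional "
                              "coordinates")
        rows = [(r[0], _element_from_label(r[0]),
                 _num(r[1]), _num(r[2]), _num(r[3])) for r in table]
    else:
        rows = [(r[0], _strip_symbol(r[1]),
                 _num(r[2]), _num(r[3]), _num(r[4])) for r in table]
    if occs and any(abs(o - 1.0) > 1e-6 for o in occs):
        raise UnsupportedFeatureError(
            "partial atom-site occupancies are not supported")

    elements = [r[1] for r in rows]
    frac = np.array([[r[2], r[3], r[4]] for r in rows], dtype=float)

    # symmetry-expand atom sites with deduplication
    all_el: list[str] = []
    all_frac: list[np.ndarray] = []
    for triplet in sym:
        rot, tran = parse_symop(triplet)
        pos = frac @ rot.T + tran
        pos -= np.floor(pos)
        for el, p in zip(elements, pos):
            dup = False
            for q in all_frac:
                d = p - q
                d -= np.round(d)
                if np.linalg.norm(cell.to_cart(d)) < 0.05:
                    dup = True
                    break
            if not dup:
                all_el.append(el)
                all_frac.append(p)
    sites = np.array(all_frac)

    mols = _assemble_molecules(cell, all_el, sites, bond_tolerance)
    struct = CrystalStructure(cell, mols, sym, None,
                              name=block.name or "structure")
    # asymmetric unit: re-derive as the molecules generated from the first
    # copy of the input sites; for simplicity keep all molecules asymmetric
    # unless expansion of the first Z/len(sym) molecules reproduces the rest.
    struct.n_asym = _infer_n_asym(struct)
    return struct


def _num(v) -> float:
    try:
        return float(gemmi.cif.as_number(v))
    except Exception as exc:
        raise FormatError(f"non-numeric CIF value {v!r}") from exc


def _strip_symbol(sym: str) -> str:
    s = "".join(ch for ch in sym if ch.isalpha())
    return s[:2].capitalize() if len(s) > 1 and s[:2].capitalize() in COVALENT_RADII else s[:1].upper()


def _element_from_label(label: str) -> str:
    s = "".join(ch for ch in label if ch.isalpha())
    two = s[:2].capitalize()
    return two if two in COVALENT_RADII else s[:1].upper()


def _assemble_molecules(cell: UnitCell, elements: list[str],
                        frac: np.ndarray,
                        bond_tolerance: float) -> list[Molecule]:
    """Bond graph over periodic images -> connected components -> molecules."""
    n = len(elements)
    radii = np.array([COVALENT_RADII.get(e, DEFAULT_RADIUS) for e in elements])
    g = nx.Graph()
    g.add_nodes_from(range(n))
    # periodic images needed so that bonds across boundaries are seen
    shifts = np.array([[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1)
                       for k in (-1, 0, 1)], dtype=float)
    cart0 = cell.to_cart(frac)
    max_bond = (radii.max() * 2) * bond_tolerance
    for s in shifts:
        cart_s = cell.to_cart(frac + s)
        d = cdist(cart0, cart_s)
        cut = (radii[:, None] + radii[None, :]) * bond_tolerance
        ii, jj = np.where(d <= cut)
        for i, j in zip(ii, jj):
            if i == j and np.allclose(s, 0):
                continue
            if d[i, j] > max_bond:
                continue
            if i != j:
                g.add_edge(int(i), int(j), shift=tuple(s))

    mols: list[Molecule] = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        # unwrap: BFS assigning each atom a lattice shift consistent with bonds
        shift_of = {comp[0]: np.zeros(3)}
        order = [comp[0]]
        queue = [comp[0]]
        while queue:
            u = queue.pop()
            for v in g.neighbors(u):
                if v in shift_of:
                    continue
                # find the image shift that places v closest to u
                best = None
                best_d = np.inf
                pu = frac[u] + shift_of[u]
                for s in shifts:
                    pv = frac[v] + s
                    dd = np.linalg.norm(cell.to_cart(pv - pu))
                    if dd < best_d:
                        best_d, best = dd, s
                shift_of[v] = np.asarray(best)
                order.append(v)
                queue.append(v)
        idx = sorted(order)
        mfrac = np.array([frac[i] + shift_of[i] for i in idx])
        mol = _wrap_molecule(Molecule("unknown", tuple(elements[i] for i in idx),
                                      mfrac))
        mols.append(mol)
    mols.sort(key=lambda m: tuple(np.round(m.centroid, 6)))
    return mols


def _infer_n_asym(struct: CrystalStructure) -> int:
    """Smallest leading molecule subset whose symmetry expansion gives Z."""
    for n in range(1, struct.Z + 1):
        try:
            exp = expand_asymmetric(struct.cell, struct.molecules[:n],
                                    struct.symmetry_xyz)
        except Exception:
            continue
        if exp.Z == struct.Z and all(
            any(_same_site(m, q, 1e-3) for q in struct.molecules)
            for m in exp.molecules
        ):
            return n
    return struct.Z


# ---------------------------------------------------------------------------
# CIF output


def write_cif(structure: CrystalStructure, path=None, *,
              header: str | None = None, asym_only: bool = False) -> str:
    """Write a structure as CIF 1.1 text; returns the text.

    By default all Z molecules are written explicitly in P1, so reading the
    file back reproduces the same molecule set.  With ``asym_only=True`` only
    the asymmetric-unit molecules are written together with the structure's
    symmetry triplet list, and the reader regenerates the rest by expansion.
    """
    buf = io.StringIO()
    w = buf.write
    if header:
        for line in header.splitlines():
            w(f"# {line}\n")
    w(f"data_{structure.name}\n")
    c = structure.cell
    w(f"_cell_length_a    {c.a:.6f}\n")
    w(f"_cell_length_b    {c.b:.6f}\n")
    w(f"_cell_length_c    {c.c:.6f}\n")
    w(f"_cell_angle_alpha {c.alpha:.6f}\n")
    w(f"_cell_angle_beta  {c.beta:.6f}\n")
    w(f"_cell_angle_gamma {c.gamma:.6f}\n")
    w("loop_\n_symmetry_equiv_pos_as_xyz\n")
    ops = structure.symmetry_xyz if asym_only else ["x,y,z"]
    for t in ops:
        w(f"'{t}'\n")
    w("loop_\n_atom_site_label\n_atom_site_type_symbol\n")
    w("_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n")
    count = 0
    mols = structure.asym_molecules if asym_only else structure.molecules
    for m in mols:
        for el, f in zip(m.elements, m.frac):
            count += 1
            w(f"{el}{count} {el} {f[0]:.6f} {f[1]:.6f} {f[2]:.6f}\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def structures_equal(s1: CrystalStructure, s2: CrystalStructure,
                     tol: float = 1e-6) -> bool:
    """Cell parameters equal and molecule atom sets match within ``tol`` Å."""
    c1, c2 = s1.cell, s2.cell
    if not np.allclose([c1.a, c1.b, c1.c, c1.alpha, c1.beta, c1.gamma],
                       [c2.a, c2.b, c2.c, c2.alpha, c2.beta, c2.gamma],
                       atol=tol):
        return False
    if s1.Z != s2.Z:
        return False
    used = set()
    for m1 in s1.molecules:
        found = False
        for j, m2 in enumerate(s2.molecules):
            if j in used or len(m1.elements) != len(m2.elements):
                continue
            d = m1.centroid - m2.centroid
            d -= np.round(d)
            if np.linalg.norm(c1.to_cart(d)) < max(tol * 10, 1e-4):
                used.add(j)
                found = True
                break
        if not found:
            return False
    return True
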