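"""Doped-supercell generation: host->guest substitution and composition.

A guest is substituted onto a host site by rigid-body least-squares
superposition (Kabsch) over the scaffold atoms the two purines share —
"maximum atom overlap" operationalized as the optimal rotation + translation
over the shared ring.  Ensembles at fixed stoichiometry enumerate the
translation-inequivalent site combinations of the supercell.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .crystal_model import (
    CrystalStructure,
    Molecule,
    MoleculeTemplate,
    build_supercell,
)
from .errors import (
    AlignmentQualityError,
    ArgumentError,
    ConsistencyError,
    IncompatibilityError,
)

HOST_SPECIES = "host"


@dataclass(frozen=True)
class Composition:
    """Guest mole fraction in the solid solution."""

    x_g: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_g <= 1.0:
            raise ArgumentError("x_g must lie in [0, 1]")

    @property
    def x_h(self) -> float:
        return 1.0 - self.x_g


@dataclass
class SolidSolutionSupercell:
    """A supercell with per-site occupancy labels and composition counts."""

    base: CrystalStructure
    occupants: list[str]

    def __post_init__(self) -> None:
        if len(self.occupants) != self.base.Z:
            raise ConsistencyError("occupants length must equal molecule count")

    @property
    def N_cell(self) -> int:
        return self.base.Z

    @property
    def N_g(self) -> int:
        return sum(1 for s in self.occupants if s != self.host_species)

    @property
    def N_h(self) -> int:
        return self.N_cell - self.N_g

    @property
    def host_species(self) -> str:
        return getattr(self, "_host_species", None) or _majority(self.occupants)

    @classmethod
    def from_pure(cls, structure: CrystalStructure,
                  host_species: str | None = None) -> "SolidSolutionSupercell":
        label = host_species or structure.molecules[0].species
        ss = cls(structure.copy(), [label] * structure.Z)
        ss._host_species = label  # type: ignore[attr-defined]
        for m in ss.base.molecules:
            m.species = label
        return ss

    def copy(self) -> "SolidSolutionSupercell":
        ss = SolidSolutionSupercell(self.base.copy(), list(self.occupants))
        ss._host_species = self.host_species  # type: ignore[attr-defined]
        return ss


def _majority(labels: list[str]) -> str:
    counts: dict[str, int] = {}
    for s in labels:
        counts[s] = counts.get(s, 0) + 1
    return max(counts, key=counts.get)


def mole_fraction(ss: SolidSolutionSupercell) -> Composition:
    """x_g = N_g / N_cell, exact."""
    if ss.N_cell < 1:
        raise ArgumentError("empty supercell")
    return Composition(ss.N_g / ss.N_cell)


# ---------------------------------------------------------------------------
# Rigid superposition


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rotation R and translation t minimising |R P + t - Q|.

    Returns (R, t, rmsd).  Proper rotations only (no reflection).
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    resid = (P @ R.T + t) - Q
    rmsd = math.sqrt((resid ** 2).sum() / len(P))
    return R, t, rmsd


def substitute(
    supercell: CrystalStructure | SolidSolutionSupercell,
    site_index: int,
    guest: MoleculeTemplate,
    *,
    rmsd_threshold: float = 0.75,
    scaffold_map: list[tuple[int, int]] | None = None,
    try_flip: bool = True,
) -> SolidSolutionSupercell:
    """Replace the host molecule at ``site_index`` with ``guest``.

    The guest template is rigid-body superposed onto the host molecule by a
    least-squares fit over the mapped scaffold atoms.  When ``try_flip`` is
    set, the scaffold mapping reversed end-to-end is also tried and kept only
    if it lowers the scaffold RMSD (a planar purine can sit "face-down").
    """
    if isinstance(supercell, CrystalStructure):
        ss = SolidSolutionSupercell.from_pure(supercell)
    else:
        ss = supercell.copy()
    if not 0 <= site_index < ss.N_cell:
        raise ArgumentError(f"site_index {site_index} out of range")
    host_mol = ss.base.molecules[site_index]

    pairs = scaffold_map
    if pairs is None:
        tmpl = host_mol.template
        if tmpl is None or not tmpl.scaffold_atoms or not guest.scaffold_atoms:
            raise IncompatibilityError(
                "no scaffold mapping between host site and guest template")
        n = min(len(tmpl.scaffold_atoms), len(guest.scaffold_atoms))
        pairs = list(zip(tmpl.scaffold_atoms[:n], guest.scaffold_atoms[:n]))
    if not pairs:
        raise IncompatibilityError("empty scaffold mapping")

    host_cart = host_mol.cart(ss.base.cell)
    h_idx = [p[0] for p in pairs]
    g_idx = [p[1] for p in pairs]
    P = guest.coords[g_idx]
    Q = host_cart[h_idx]
    R, t, rmsd = kabsch(P, Q)
    if try_flip and len(pairs) >= 3:
        R2, t2, rmsd2 = kabsch(P[::-1], Q)
        if rmsd2 < rmsd:
            R, t, rmsd = R2, t2, rmsd2
            # reversal of the correspondence, not of the guest geometry
            P = P[::-1]
    if rmsd > rmsd_threshold:
        raise AlignmentQualityError(
            f"scaffold RMSD {rmsd:.3f} Å exceeds threshold {rmsd_threshold}")

    placed_cart = guest.coords @ R.T + t
    inv = np.linalg.inv(ss.base.cell.matrix)
    placed_frac = placed_cart @ inv.T
    new_mol = Molecule(guest.name, guest.elements, placed_frac, guest)
    ss.base.molecules[site_index] = new_mol
    ss.occupants[site_index] = guest.name
    ss.scaffold_rmsd = rmsd  # type: ignore[attr-defined]
    return ss


def restore_host(ss: SolidSolutionSupercell, site_index: int,
                 host: MoleculeTemplate,
                 original: CrystalStructure) -> SolidSolutionSupercell:
    """Reverse a substitution by restoring the original molecule at a site."""
    out = ss.copy()
    out.base.molecules[site_index] = original.molecules[site_index]
    out.occupants[site_index] = out.host_species
    return out


# ---------------------------------------------------------------------------
# Configuration ensembles


@dataclass
class ConfigurationEnsemble:
    """Supercell occupancy patterns at a single composition."""

    members: list[SolidSolutionSupercell]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.members:
            n_cell = self.members[0].N_cell
            n_g = self.members[0].N_g
            for m in self.members:
                if m.N_cell != n_cell or m.N_g != n_g:
                    raise ConsistencyError(
                        "ensemble members must share N_cell and N_g")


def _site_grid(structure: CrystalStructure) -> tuple[tuple[int, int, int], int]:
    repeats = getattr(structure, "repeats", (1, 1, 1))
    parent_z = getattr(structure, "parent_Z",
                       structure.Z // math.prod(repeats))
    return repeats, parent_z


def canonical_pattern(sites: tuple[int, ...], repeats: tuple[int, int, int],
                      parent_z: int) -> tuple[int, ...]:
    """Lexicographically smallest lattice translate of an occupancy pattern.

    Sites are flat indices in the cell-major order produced by
    :func:`~xtalloy.crystal_model.build_supercell`.
    """
    na, nb, nc = repeats

    def split(s: int) -> tuple[int, int, int, int]:
        m = s % parent_z
        cell = s // parent_z
        k = cell % nc
        j = (cell // nc) % nb
        i = cell // (nc * nb)
        return i, j, k, m

    def join(i: int, j: int, k: int, m: int) -> int:
        return ((i * nb + j) * nc + k) * parent_z + m

    best: tuple[int, ...] | None = None
    for di in range(na):
        for dj in range(nb):
            for dk in range(nc):
                moved = tuple(sorted(
                    join((i + di) % na, (j + dj) % nb, (k + dk) % nc, m)
                    for i, j, k, m in map(split, sites)))
                if best is None or moved < best:
                    best = moved
    assert best is not None
    return best


def enumerate_patterns(n_sites: int, n_guest: int,
                       repeats: tuple[int, int, int],
                       parent_z: int) -> list[tuple[int, ...]]:
    """All translation-inequivalent guest-site combinations (exhaustive)."""
    reps: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    for combo in itertools.combinations(range(n_sites), n_guest):
        canon = canonical_pattern(combo, repeats, parent_z)
        if canon not in reps:
            reps.add(canon)
            out.append(canon)
    return out


def enumerate_configurations(
    supercell: CrystalStructure,
    guest: MoleculeTemplate,
    n_guest: int,
    *,
    permute_axes: bool = False,
    max_members: int = 64,
    seed: int = 0,
    rmsd_threshold: float = 0.75,
) -> ConfigurationEnsemble:
    """Generate the ensemble of doped supercells at one stoichiometry.

    Covers all translation-inequivalent site combinations; when the count
    exceeds ``max_members`` a deterministic seeded uniform subsample is kept.
    With ``permute_axes`` the supercell shape with the a/b repeats swapped is
    sampled as well (equal volume, different periodicity).
    """
    if not 0 <= n_guest <= supercell.Z:
        raise ArgumentError(f"n_guest {n_guest} out of range 0..{supercell.Z}")
    repeats, parent_z = _site_grid(supercell)
    rng = np.random.default_rng(seed)

    jobs: list[tuple[CrystalStructure, tuple[int, int, int], str]] = [
        (supercell, repeats, "base")]
    if permute_axes and repeats[0] != repeats[1]:
        parent = getattr(supercell, "parent", None)
        if parent is not None:
            swapped = (repeats[1], repeats[0], repeats[2])
            jobs.append((build_supercell(parent, swapped), swapped, "ab-swap"))

    members: list[SolidSolutionSupercell] = []
    provenance: list[dict] = []
    for struct, reps, tag in jobs:
        if math.comb(struct.Z, n_guest) <= 20_000:
            patterns = enumerate_patterns(struct.Z, n_guest, reps, parent_z)
            if len(patterns) > max_members:
                idx = rng.choice(len(patterns), size=max_members,
                                 replace=False)
                patterns = [patterns[i] for i in sorted(idx)]
        else:
            # combination space too large to enumerate: seeded rejection
            # sampling of distinct translation-canonical patterns
            seen: set[tuple[int, ...]] = set()
            patterns = []
            attempts = 0
            while len(patterns) < max_members and attempts < 50 * max_members:
                attempts += 1
                combo = tuple(sorted(rng.choice(struct.Z, size=n_guest,
                                                replace=False)))
                canon = canonical_pattern(combo, reps, parent_z)
                if canon not in seen:
                    seen.add(canon)
                    patterns.append(canon)
        for pat in patterns:
            ss = SolidSolutionSupercell.from_pure(struct)
            for s in pat:
                ss = substitute(ss, s, guest, rmsd_threshold=rmsd_threshold)
            members.append(ss)
            provenance.append({"sites": list(pat), "repeats": list(reps),
                               "cell": tag, "seed": seed})
    return ConfigurationEnsemble(members, provenance)
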