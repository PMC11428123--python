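"""Coarse-grained stochastic crystal growth on the interaction graph.

Growth units are whole molecules on the perfect-crystal site lattice (cells
x molecules-per-cell); no vacancies in the bulk, no surface reconstruction.
Each cycle picks a random surface site — an empty site adjacent to the
crystal (attachment candidate) or an occupied site with an empty neighbor
(detachment candidate), uniformly over the union — and accepts with the
Metropolis pair

    P_attach = min(1, exp(+beta (U_i + dmu)))
    P_detach = min(1, exp(-beta (U_i + dmu)))

where U_i = sum of ΔG_cryst over occupied neighbors (positive = favorable
to crystallize), beta = 1/RT, and dmu the driving force, so the
attach/detach rate ratio is exp(beta (U_i + dmu)) and single-site detailed
balance holds.  Detachments that would disconnect the crystal are rejected.

Driving-force schedule: constant at the initial supersaturation, then a
linear descent between the two breakpoints, then equilibrium.  Because
ΔG_cryst > 0 for every crystal contact, a literal dmu = 0 still biases
attachment everywhere; the default ``equilibrium_mode="solubility_matched"``
therefore offsets the schedule by the kink (half-crystal) energy
U_kink = 1/2 Σ mult·ΔG_cryst, so "equilibrium" means coexistence.
``fixed_zero`` applies the raw schedule unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import ConvexHull

from .crystal_model import CrystalStructure
from .errors import (
    ArgumentError,
    ConfigError,
    ConsistencyError,
    MetricsUndefinedError,
)
from .interactions import InteractionTable

R_KJ = 8.314e-3  # kJ mol^-1 K^-1
KCAL_TO_KJ = 4.184


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class GrowthConfig:
    """Growth-run parameters.

    Defaults follow the reference protocol: 10^6 growth/dissolution cycles
    with an initial driving force of 100 kcal/mol, descending to equilibrium
    between cycles 5x10^5 and 6x10^5.  Desk-scale presets (see
    :mod:`xtalloy.pipeline`) use far fewer cycles, a smaller box and a
    moderate initial driving force.
    """

    total_iterations: int = 1_000_000
    dmu_initial: float = 100.0 * KCAL_TO_KJ  # kJ/mol
    descent_start: int = 500_000
    equilibrium_iteration: int = 600_000
    temperature: float = 300.0
    seed: int = 0
    guest_fraction: float | None = None
    nucleus: tuple[int, int, int] = (3, 3, 3)
    box: tuple[int, int, int] = (40, 24, 22)
    equilibrium_mode: str = "solubility_matched"
    #: if set, overrides dmu_initial with this multiple of the kink energy
    #: U_kink of the supplied table, so the supersaturation scales with the
    #: interaction strength of the system being grown
    dmu_relative: float | None = None
    #: end the run when the crystal first reaches the box margin (finite
    #: crystals at coexistence dissolve, so pressing on is never informative)
    stop_at_wall: bool = True
    #: end the run once the crystal reaches this many sites (None = no cap)
    max_sites: int | None = None
    log_every: int = 5000
    debug_check_connectivity: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.descent_start < self.equilibrium_iteration
                <= self.total_iterations):
            raise ConfigError("need 0 < descent_start < equilibrium "
                              "<= total_iterations")
        if self.dmu_initial < 0:
            raise ConfigError("driving force must be >= 0")
        if self.equilibrium_mode not in ("solubility_matched", "fixed_zero"):
            raise ConfigError("equilibrium_mode must be solubility_matched "
                              "or fixed_zero")


def schedule_driving_force(config: GrowthConfig, iteration: int) -> float:
    """Supersaturation Δμ (kJ/mol) at a given cycle: constant, then a linear
    descent between the breakpoints, then 0."""
    if not 0 <= iteration <= config.total_iterations:
        raise ArgumentError("iteration out of range")
    if iteration < config.descent_start:
        return config.dmu_initial
    if iteration >= config.equilibrium_iteration:
        return 0.0
    span = config.equilibrium_iteration - config.descent_start
    frac = (iteration - config.descent_start) / span
    return config.dmu_initial * (1.0 - frac)


# ---------------------------------------------------------------------------
# Random-access candidate set


class _ListDict:
    """Set with O(1) insert/discard and uniform random choice."""

    __slots__ = ("items", "pos")

    def __init__(self) -> None:
        self.items: list[int] = []
        self.pos: dict[int, int] = {}

    def add(self, x: int) -> None:
        if x not in self.pos:
            self.pos[x] = len(self.items)
            self.items.append(x)

    def discard(self, x: int) -> None:
        i = self.pos.pop(x, None)
        if i is None:
            return
        last = self.items.pop()
        if i < len(self.items):
            self.items[i] = last
            self.pos[last] = i

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, x: int) -> bool:
        return x in self.pos

    def choose(self, rng: np.random.Generator) -> int:
        return self.items[int(rng.integers(len(self.items)))]


# ---------------------------------------------------------------------------
# Growth state and engine

EMPTY, HOST, GUEST = 0, 1, 2


@dataclass
class GrowthState:
    """Final occupancy lattice plus bookkeeping from a growth run."""

    structure: CrystalStructure
    occupancy: np.ndarray  # (nx, ny, nz, Z) uint8
    config: GrowthConfig
    size_log: list[tuple[int, int]] = field(default_factory=list)
    events: dict = field(default_factory=dict)

    @property
    def n_occupied(self) -> int:
        return int((self.occupancy != EMPTY).sum())

    def occupied_indices(self) -> np.ndarray:
        return np.argwhere(self.occupancy != EMPTY)

    def centroids_cart(self) -> np.ndarray:
        """Cartesian centroids of all occupied sites."""
        idx = self.occupied_indices()
        cents = np.array([m.centroid for m in self.structure.molecules])
        frac = idx[:, :3] + cents[idx[:, 3]]
        return frac @ self.structure.cell.matrix.T

    def species_labels(self) -> np.ndarray:
        idx = self.occupied_indices()
        return self.occupancy[idx[:, 0], idx[:, 1], idx[:, 2], idx[:, 3]]

    def to_xyz(self, path) -> None:
        cart = self.centroids_cart()
        kinds = self.species_labels()
        with open(path, "w") as fh:
            fh.write(f"{len(cart)}\n")
            fh.write("site centroids: C=host N=guest\n")
            for p, k in zip(cart, kinds):
                el = "C" if k == HOST else "N"
                fh.write(f"{el} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")


class GrowthSimulation:
    """KMC engine on the neighbor graph of a crystal structure."""

    def __init__(self, table: InteractionTable, structure: CrystalStructure,
                 config: GrowthConfig,
                 guest_table: InteractionTable | None = None) -> None:
        if not table.types:
            raise ConfigError("empty interaction table")
        if not table.contacts:
            raise ConfigError("interaction table carries no contacts; build "
                              "it from enumerate_neighbors/classify_unique")
        self.table = table
        self.structure = structure
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.Z = structure.Z
        self.nx, self.ny, self.nz = config.box

        # per-molecule neighbor stencil: (di,dj,dk,m2,type_id)
        self.stencil: list[list[tuple[int, int, int, int, int]]] = [
            [] for _ in range(self.Z)]
        for c in table.contacts:
            tid = table.contact_type.get(c.key())
            if tid is None:
                raise ConfigError(f"contact {c.key()} has no type assignment")
            self.stencil[c.central].append(
                (c.offset[0], c.offset[1], c.offset[2], c.neighbor, tid))
        dg = {}
        for t in table.types:
            if t.dg_cryst is None:
                raise ConfigError("interaction table has unset ΔG_cryst")
            dg[t.type_id] = t.dg_cryst
        self.dg_host = dg
        if guest_table is not None:
            self.dg_guest = {t.type_id: t.dg_cryst for t in guest_table.types}
        else:
            self.dg_guest = dg
        self.u_kink = 0.5 * sum(t.multiplicity * t.dg_cryst
                                for t in table.types)
        self.beta = 1.0 / (R_KJ * config.temperature)
        if config.dmu_relative is not None:
            self.config = config = replace(
                config, dmu_initial=abs(config.dmu_relative * self.u_kink))

        self.occ = np.zeros((self.nx, self.ny, self.nz, self.Z),
                            dtype=np.uint8)
        self.attach_set = _ListDict()
        self.detach_set = _ListDict()
        self.forced_equilibrium = False
        if all(abs(v) < 1e-12 for v in dg.values()) and config.dmu_initial == 0:
            import warnings
            warnings.warn("all ΔG_cryst zero with zero driving force: "
                          "growth is a pure random walk")

    # -- site indexing ------------------------------------------------------

    def flat(self, i: int, j: int, k: int, m: int) -> int:
        return ((i * self.ny + j) * self.nz + k) * self.Z + m

    def unflat(self, s: int) -> tuple[int, int, int, int]:
        m = s % self.Z
        s //= self.Z
        k = s % self.nz
        s //= self.nz
        return s // self.ny, s % self.ny, k, m

    def neighbors(self, i: int, j: int, k: int, m: int):
        for di, dj, dk, m2, tid in self.stencil[m]:
            i2, j2, k2 = i + di, j + dj, k + dk
            if 0 <= i2 < self.nx and 0 <= j2 < self.ny and 0 <= k2 < self.nz:
                yield i2, j2, k2, m2, tid

    # -- energies -----------------------------------------------------------

    def site_energy(self, i: int, j: int, k: int, m: int,
                    species: int = HOST) -> float:
        dg = self.dg_host if species == HOST else self.dg_guest
        u = 0.0
        for i2, j2, k2, m2, tid in self.neighbors(i, j, k, m):
            if self.occ[i2, j2, k2, m2] != EMPTY:
                u += dg[tid]
        return u

    # -- surface bookkeeping ------------------------------------------------

    def _refresh_candidacy(self, i: int, j: int, k: int, m: int) -> None:
        s = self.flat(i, j, k, m)
        occupied = self.occ[i, j, k, m] != EMPTY
        has_occ = False
        has_empty = False
        for i2, j2, k2, m2, _ in self.neighbors(i, j, k, m):
            if self.occ[i2, j2, k2, m2] != EMPTY:
                has_occ = True
            else:
                has_empty = True
        if occupied:
            self.attach_set.discard(s)
            if has_empty:
                self.detach_set.add(s)
            else:
                self.detach_set.discard(s)
        else:
            self.detach_set.discard(s)
            if has_occ:
                self.attach_set.add(s)
            else:
                self.attach_set.discard(s)

    def _update_around(self, i: int, j: int, k: int, m: int) -> None:
        self._refresh_candidacy(i, j, k, m)
        for i2, j2, k2, m2, _ in self.neighbors(i, j, k, m):
            self._refresh_candidacy(i2, j2, k2, m2)

    # -- nucleation ---------------------------------------------------------

    def seed_nucleus(self) -> None:
        ni, nj, nk = self.config.nucleus
        ci = (self.nx - ni) // 2
        cj = (self.ny - nj) // 2
        ck = (self.nz - nk) // 2
        for i in range(ci, ci + ni):
            for j in range(cj, cj + nj):
                for k in range(ck, ck + nk):
                    for m in range(self.Z):
                        self.occ[i, j, k, m] = HOST
        for i in range(ci - 1, ci + ni + 1):
            for j in range(cj - 1, cj + nj + 1):
                for k in range(ck - 1, ck + nk + 1):
                    if (0 <= i < self.nx and 0 <= j < self.ny
                            and 0 <= k < self.nz):
                        for m in range(self.Z):
                            self._refresh_candidacy(i, j, k, m)

    def single_site_occupancy(self, site: tuple[int, int, int, int],
                              cycles: int, dmu: float = 0.0,
                              burn_in: int = 1000) -> float:
        """Long-run occupancy of one site with its surroundings frozen.

        Repeatedly proposes attach/detach at ``site`` with the engine's own
        energies and acceptance rule; every other site is held fixed.  The
        stationary occupancy of the two-state chain is
        e^{β(U+Δμ)} / (1 + e^{β(U+Δμ)}).
        """
        i, j, k, m = site
        rng = self.rng
        occupied = self.occ[i, j, k, m] != EMPTY
        hits = 0
        for step in range(cycles + burn_in):
            u = self.site_energy(i, j, k, m)
            arg = self.beta * (u + dmu) * (1.0 if not occupied else -1.0)
            if arg >= 0 or rng.random() < math.exp(arg):
                occupied = not occupied
            if step >= burn_in and occupied:
                hits += 1
        return hits / cycles

    # -- connectivity -------------------------------------------------------

    def _detach_disconnects(self, i: int, j: int, k: int, m: int) -> bool:
        """Would removing this occupied site split the crystal?"""
        occ_nb = [(i2, j2, k2, m2)
                  for i2, j2, k2, m2, _ in self.neighbors(i, j, k, m)
                  if self.occ[i2, j2, k2, m2] != EMPTY]
        if len(occ_nb) <= 1:
            # sole site of the crystal may not detach either
            return (self.occ != EMPTY).sum() - 1 == 0 and len(occ_nb) == 0
        removed = (i, j, k, m)
        targets = set(occ_nb[1:])
        seen = {occ_nb[0], removed}
        stack = [occ_nb[0]]
        while stack and targets:
            ci, cj, ck, cm = stack.pop()
            for nb in self.neighbors(ci, cj, ck, cm):
                node = nb[:4]
                if node in seen or self.occ[node] == EMPTY:
                    continue
                seen.add(node)
                targets.discard(node)
                stack.append(node)
        return bool(targets)

    def _assert_connected(self) -> None:
        occ_sites = list(map(tuple, np.argwhere(self.occ != EMPTY)))
        if not occ_sites:
            return
        seen = {occ_sites[0]}
        stack = [occ_sites[0]]
        while stack:
            ci, cj, ck, cm = stack.pop()
            for nb in self.neighbors(ci, cj, ck, cm):
                node = nb[:4]
                if node not in seen and self.occ[node] != EMPTY:
                    seen.add(node)
                    stack.append(node)
        if len(seen) != len(occ_sites):
            raise ConsistencyError("crystal disconnected")  # pragma: no cover

    # -- main loop ----------------------------------------------------------

    def effective_bias(self, iteration: int) -> float:
        dmu = 0.0 if self.forced_equilibrium else \
            schedule_driving_force(self.config, iteration)
        if self.config.equilibrium_mode == "solubility_matched":
            return dmu - self.u_kink
        return dmu

    def run(self) -> GrowthState:
        cfg = self.config
        self.seed_nucleus()
        rng = self.rng
        size = self.n_occupied = int((self.occ != EMPTY).sum())
        log: list[tuple[int, int]] = [(0, size)]
        attempts = {"attach": 0, "detach": 0, "accept_attach": 0,
                    "accept_detach": 0, "reject_disconnect": 0}
        gf = cfg.guest_fraction or 0.0

        for it in range(cfg.total_iterations):
            na, nd = len(self.attach_set), len(self.detach_set)
            tot = na + nd
            if tot == 0:
                break
            bias = self.effective_bias(it)
            pick = int(rng.integers(tot))
            if pick < na:
                s = self.attach_set.items[pick]
                i, j, k, m = self.unflat(s)
                if cfg.stop_at_wall and (
                        i <= 0 or i >= self.nx - 1 or j <= 0
                        or j >= self.ny - 1 or k <= 0 or k >= self.nz - 1):
                    # hard wall: the outermost cell shell never fills.
                    # With stop_at_wall=False the box edge merely truncates
                    # the neighbor graph (bulk/slab mode).
                    continue
                species = GUEST if (gf > 0 and rng.random() < gf) else HOST
                u = self.site_energy(i, j, k, m, species)
                attempts["attach"] += 1
                arg = self.beta * (u + bias)
                if arg >= 0 or rng.random() < math.exp(arg):
                    self.occ[i, j, k, m] = species
                    size += 1
                    attempts["accept_attach"] += 1
                    self._update_around(i, j, k, m)
                    if (cfg.stop_at_wall
                            and (i <= 1 or i >= self.nx - 2 or j <= 1
                                 or j >= self.ny - 2 or k <= 1
                                 or k >= self.nz - 2)):
                        attempts["hit_wall"] = it
                        break
                    if cfg.max_sites is not None and size >= cfg.max_sites:
                        attempts["size_cap"] = it
                        break
            else:
                s = self.detach_set.items[pick - na]
                i, j, k, m = self.unflat(s)
                species = int(self.occ[i, j, k, m])
                u = self.site_energy(i, j, k, m, species)
                attempts["detach"] += 1
                arg = -self.beta * (u + bias)
                if arg >= 0 or rng.random() < math.exp(arg):
                    if size > 1 and self._detach_disconnects(i, j, k, m):
                        attempts["reject_disconnect"] += 1
                    elif size == 1:
                        pass  # never dissolve the last site
                    else:
                        self.occ[i, j, k, m] = EMPTY
                        size -= 1
                        attempts["accept_detach"] += 1
                        self._update_around(i, j, k, m)
                        if cfg.debug_check_connectivity:
                            self._assert_connected()
            if cfg.log_every and (it + 1) % cfg.log_every == 0:
                log.append((it + 1, size))
        log.append((cfg.total_iterations, size))
        return GrowthState(self.structure, self.occ, cfg, log, attempts)


def run_growth(table: InteractionTable, structure: CrystalStructure,
               config: GrowthConfig,
               guest_table: InteractionTable | None = None) -> GrowthState:
    """Grow a single crystal; identical seeds give identical trajectories."""
    sim = GrowthSimulation(table, structure, config, guest_table)
    return sim.run()


# ---------------------------------------------------------------------------
# Facet identification


def _candidate_families(structure: CrystalStructure,
                        candidates=None) -> dict[tuple, np.ndarray]:
    """Candidate plane families -> unit plane normal (Cartesian).

    Indices are reduced to coprime form and signed canonically; (hkl) and
    (-h,-k,-l) are the same family.
    """
    if candidates is None:
        rng2 = range(-2, 3)
        candidates = [(h, k, l) for h in rng2 for k in rng2 for l in rng2
                      if (h, k, l) != (0, 0, 0)]
    inv_t = np.linalg.inv(structure.cell.matrix).T
    fams: dict[tuple, np.ndarray] = {}
    for hkl in candidates:
        g = math.gcd(math.gcd(abs(hkl[0]), abs(hkl[1])), abs(hkl[2]))
        red = tuple(x // g for x in hkl)
        for x in red:
            if x > 0:
                break
            if x < 0:
                red = tuple(-y for y in red)
                break
        if red in fams:
            continue
        n = inv_t @ np.array(red, float)
        fams[red] = n / np.linalg.norm(n)
    return fams


def identify_facets(state: GrowthState, structure: CrystalStructure | None = None,
                    candidates=None, neighborhood: float = 6.0,
                    self_weight: float = 2.0) -> dict[tuple, float]:
    """Assign surface sites to plane families by local surface normals.

    Every occupied site with an empty (or out-of-box) neighbor on the
    molecular contact graph is a surface site; its raw outward direction is
    the Cartesian sum of the vectors toward its empty neighbors.  The local
    normal is the average of raw outward directions over the surface sites
    within ``neighborhood`` Å (a least-squares surface patch fit in the
    direction domain), and each site votes for the candidate plane family
    nearest in angle.  Returns relative areas as site-count fractions.
    """
    structure = structure or state.structure
    surf_pts, out_dirs = _surface_sites(state, structure)
    if len(surf_pts) < 4:
        raise MetricsUndefinedError("crystal too small to classify facets")
    fams = _candidate_families(structure, candidates)
    labels = list(fams)
    normals = np.array([fams[f] for f in labels])

    from scipy.spatial import cKDTree
    tree = cKDTree(surf_pts)
    votes = np.zeros(len(labels))
    for p, d in zip(surf_pts, out_dirs):
        idx = tree.query_ball_point(p, neighborhood)
        n = out_dirs[idx].sum(axis=0) + (self_weight - 1.0) * d
        nrm = np.linalg.norm(n)
        if nrm < 1e-9:
            n = d
            nrm = np.linalg.norm(n)
            if nrm < 1e-9:
                continue
        n = n / nrm
        votes[int(np.argmax(np.abs(normals @ n)))] += 1.0
    total = votes.sum()
    if total == 0:
        raise MetricsUndefinedError("no classifiable surface sites")
    return {lab: float(v / total) for lab, v in zip(labels, votes) if v > 0}


def _surface_sites(state: GrowthState, structure: CrystalStructure
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian centroids + raw outward directions of surface sites.

    Surface = occupied sites with at least one empty (or out-of-box)
    neighbor on the molecular contact graph.
    """
    from .interactions import enumerate_neighbors
    occ = state.occupancy
    nx, ny, nz, Z = occ.shape
    cell = structure.cell
    cents = np.array([m.centroid for m in structure.molecules])
    stencil: list[list[tuple[int, int, int, int, np.ndarray]]] = [
        [] for _ in range(Z)]
    for c in enumerate_neighbors(structure):
        vec = cell.to_cart(np.array(c.frac_vector))
        stencil[c.central].append((c.offset[0], c.offset[1], c.offset[2],
                                   c.neighbor, vec / np.linalg.norm(vec)))
    pts = []
    dirs = []
    m_cart = cell.matrix
    for i, j, k, m in np.argwhere(occ != EMPTY):
        out = np.zeros(3)
        exposed = False
        for di, dj, dk, m2, u in stencil[m]:
            i2, j2, k2 = i + di, j + dj, k + dk
            if (0 <= i2 < nx and 0 <= j2 < ny and 0 <= k2 < nz
                    and occ[i2, j2, k2, m2] != EMPTY):
                continue
            exposed = True
            out += u
        if exposed:
            frac = np.array([i, j, k], float) + cents[m]
            pts.append(m_cart @ frac)
            nrm = np.linalg.norm(out)
            dirs.append(out / nrm if nrm > 0 else out)
    return np.array(pts), np.array(dirs)


# ---------------------------------------------------------------------------
# Morphology metrics


HEXAGONAL = "hexagonal"
RECTANGULAR = "square/rectangular"
LATH = "lath"
IRREGULAR = "irregular polygon"


@dataclass
class MorphologyReport:
    facet_areas: dict[tuple, float]
    extents: tuple[float, float, float]  # along a, b, c directions (Å)
    aspect_ratios: tuple[float, float]  # a/b', a/c' (principal in-plane)
    cross_section: str
    habit: str
    n_sites: int
    hull_edges: int = 0

    def to_dict(self) -> dict:
        return {
            "facet_areas": {"".join(map(str, k)): v
                            for k, v in self.facet_areas.items()},
            "extents": list(self.extents),
            "aspect_ratios": list(self.aspect_ratios),
            "cross_section": self.cross_section,
            "habit": self.habit,
            "n_sites": self.n_sites,
        }


def _merged_hull_edges(pts2: np.ndarray, angle_tol_deg: float = 28.0):
    """Convex hull of 2D points with near-collinear edges merged.

    Returns (lengths, unit directions) of the merged edges in hull order.
    """
    try:
        hull = ConvexHull(pts2)
    except Exception as exc:  # qhull degeneracy: collinear projection
        raise MetricsUndefinedError(
            f"degenerate in-plane projection: {exc}") from exc
    verts = pts2[hull.vertices]
    n = len(verts)
    edges = [verts[(i + 1) % n] - verts[i] for i in range(n)]
    lengths = [float(np.linalg.norm(e)) for e in edges]
    dirs = [e / l if l > 0 else e for e, l in zip(edges, lengths)]
    merged: list[float] = []
    merged_dirs: list[np.ndarray] = []
    for d, l in zip(dirs, lengths):
        if merged and float(np.dot(d, merged_dirs[-1])) > math.cos(
                math.radians(angle_tol_deg)):
            w = merged[-1]
            merged_dirs[-1] = (merged_dirs[-1] * w + d * l)
            merged_dirs[-1] /= np.linalg.norm(merged_dirs[-1])
            merged[-1] = w + l
        else:
            merged.append(l)
            merged_dirs.append(d)
    # wrap-around merge
    if len(merged) > 1 and float(np.dot(merged_dirs[0], merged_dirs[-1])) \
            > math.cos(math.radians(angle_tol_deg)):
        merged[0] += merged.pop()
        merged_dirs.pop()
    return merged, merged_dirs


def _dominant_directions(lengths, dirs, angle_tol_deg: float = 28.0,
                         frac: float = 0.10):
    """Cluster hull edges by direction (mod 180°); a direction is dominant
    when its edges carry >= 2*frac of the perimeter (a convex polygon's
    edges come in near-antiparallel pairs, each >= frac)."""
    perim = sum(lengths)
    clusters: list[tuple[np.ndarray, float]] = []
    cos_tol = math.cos(math.radians(angle_tol_deg))
    for d, l in zip(dirs, lengths):
        for i, (cd, cl) in enumerate(clusters):
            if abs(float(np.dot(d, cd))) > cos_tol:
                sgn = 1.0 if float(np.dot(d, cd)) > 0 else -1.0
                nd = cd * cl + sgn * d * l
                clusters[i] = (nd / np.linalg.norm(nd), cl + l)
                break
        else:
            clusters.append((d, l))
    return [cl for _, cl in clusters if cl >= 2 * frac * perim]


def morphology_metrics(state: GrowthState,
                       structure: CrystalStructure | None = None,
                       facet_candidates=None) -> MorphologyReport:
    """Axis extents, aspect ratios, cross-section class and facet areas.

    Extents are spans of occupied-site centroids along the a, b, c cell
    directions.  The cross-section is the convex hull of the projection onto
    the plane ⊥ a; its polygon class counts merged hull edges carrying
    >= 10% of the perimeter: 6 -> hexagonal, 4 -> square/rectangular
    (aspect <= 2) or lath (aspect > 2), else irregular.
    """
    structure = structure or state.structure
    pts = state.centroids_cart()
    if len(pts) <= 2:
        raise MetricsUndefinedError("morphology undefined for <= 2 sites")
    m = structure.cell.matrix
    axes = m / np.linalg.norm(m, axis=0)
    cents = np.array([mol.centroid for mol in structure.molecules])
    spans = []
    for ax in range(3):
        proj = pts @ axes[:, ax]
        # pad the centroid span by one site spacing so a single unit cell
        # reports the cell edge length
        levels = len(np.unique(np.round(cents[:, ax] % 1.0, 6)))
        pad = np.linalg.norm(m[:, ax]) / max(levels, 1)
        spans.append(float(proj.max() - proj.min()) + pad)
    # in-plane basis perpendicular to a
    u1 = axes[:, 0]
    tmp = axes[:, 1] - (axes[:, 1] @ u1) * u1
    u2 = tmp / np.linalg.norm(tmp)
    u3 = np.cross(u1, u2)
    pts2 = np.column_stack([pts @ u2, pts @ u3])

    lengths, dirs = _merged_hull_edges(pts2)
    dominant = _dominant_directions(lengths, dirs)
    # principal in-plane extents
    centered = pts2 - pts2.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, _ = np.linalg.eigh(cov)
    p_long = 2 * math.sqrt(max(evals[1], 1e-12) * 3)
    p_short = 2 * math.sqrt(max(evals[0], 1e-12) * 3)
    inplane_aspect = p_long / max(p_short, 1e-9)

    # dominant edge directions pair into antiparallel hull edges: 3
    # directions = 6 dominant edges (hexagon), 2 = 4 edges (rectangle/lath)
    nd = len(dominant)
    if nd == 3:
        cls = HEXAGONAL
    elif nd == 2:
        cls = RECTANGULAR if inplane_aspect <= 2.0 else LATH
    elif nd == 1:
        cls = LATH
    else:
        cls = IRREGULAR

    ea = spans[0]
    ratio = ea / max(p_long, 1e-9)
    if ratio >= 3.0:
        habit = "needle"
    elif ratio >= 1.5:
        habit = "rod"
    elif ratio <= 0.6:
        habit = "plate"
    else:
        habit = "prism"

    try:
        fac = identify_facets(state, structure, facet_candidates)
    except MetricsUndefinedError:
        fac = {}
    return MorphologyReport(fac, (spans[0], spans[1], spans[2]),
                            (ea / max(p_long, 1e-9), ea / max(p_short, 1e-9)),
                            cls, habit, len(pts), len(lengths))


# ---------------------------------------------------------------------------
# Parameter sweep


def sweep_morphology(base_table: InteractionTable,
                     structure: CrystalStructure,
                     pi_scales, ratio_3h_2h, config: GrowthConfig,
                     replicates: int = 3):
    """Median morphology metrics over a π-stack / 3H:2H parameter grid.

    Returns a list of dicts with grid coordinates, median a-axis aspect and
    extents, and the modal cross-section class over seeded replicates.
    """
    if replicates < 3:
        raise ArgumentError("need >= 3 replicates")
    results = []
    for pi_s in pi_scales:
        for ratio in ratio_3h_2h:
            reports = []
            for r in range(replicates):
                table = _scaled_table(base_table, pi_s, ratio)
                cfg = replace(config, seed=config.seed + 1000 * r + 1)
                state = run_growth(table, structure, cfg)
                reports.append(morphology_metrics(state, structure))
            med_aspect = float(np.median([rep.aspect_ratios[0]
                                          for rep in reports]))
            med_ext = tuple(float(np.median([rep.extents[i]
                                             for rep in reports]))
                            for i in range(3))
            classes = [rep.cross_section for rep in reports]
            modal = max(set(classes), key=classes.count)
            results.append({"pi_scale": pi_s, "ratio_3h_2h": ratio,
                            "median_a_aspect": med_aspect,
                            "median_extents": med_ext,
                            "cross_section": modal})
    return results


def _scaled_table(table: InteractionTable, pi_scale: float,
                  ratio_3h_2h: float) -> InteractionTable:
    """Scale π-stack ΔG_cryst and set the 3H:2H ratio (2H kept fixed)."""
    from dataclasses import replace as drep
    new_types = []
    for t in table.types:
        if t.label == "π-stack":
            new_types.append(drep(t, dg_cryst=t.dg_cryst * pi_scale))
        elif t.label == "3H-bond":
            base_2h = next((x.dg_cryst for x in table.types
                            if x.label == "2H-bond"), t.dg_cryst)
            new_types.append(drep(t, dg_cryst=base_2h * ratio_3h_2h))
        else:
            new_types.append(drep(t))
    return InteractionTable(table.structure_id, new_types, table.solvent,
                            dict(table.contact_type), list(table.contacts))
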