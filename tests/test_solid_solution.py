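import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from xtalloy.crystal_model import (
    CrystalStructure,
    Molecule,
    UnitCell,
    build_supercell,
)
from xtalloy.errors import ArgumentError, IncompatibilityError
from xtalloy.solid_solution import (
    SolidSolutionSupercell,
    canonical_pattern,
    enumerate_configurations,
    enumerate_patterns,
    kabsch,
    mole_fraction,
    substitute,
)
from xtalloy.synthetic_data import (
    guest_toy_template,
    make_toy_structure,
    purine_template,
)


class TestSubstitute:
    def test_self_substitution_zero_rmsd(self, toy_beta4):
        sc = build_supercell(toy_beta4, (3, 3, 1))
        guest = guest_toy_template("hpx")
        ss = substitute(sc, 0, guest)
        assert ss.scaffold_rmsd == pytest.approx(0.0, abs=1e-9)
        assert (ss.N_g, ss.N_h, ss.N_cell) == (1, 35, 36)

    def test_purine_superposition_matches_scipy_oracle(self):
        """Scaffold RMSD equals the closed-form rigid-superposition optimum
        computed independently with scipy's align_vectors."""
        host_t = purine_template("guanine")
        guest_t = purine_template("hypoxanthine")
        cell = UnitCell(25, 25, 25)
        rng = np.random.default_rng(11)
        # place the host with a random rotation + translation
        rot = Rotation.random(random_state=7).as_matrix()
        coords = host_t.coords @ rot.T + rng.uniform(5, 15, 3)
        inv = np.linalg.inv(cell.matrix)
        mol = Molecule("guanine", host_t.elements, coords @ inv.T, host_t)
        struct = CrystalStructure(cell, [mol], ["x,y,z"], 1, "host")
        ss = substitute(struct, 0, guest_t, try_flip=False)

        P = guest_t.coords[list(guest_t.scaffold_atoms)]
        Q = coords[list(host_t.scaffold_atoms)]
        r, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        oracle_rmsd = rssd / math.sqrt(len(P))
        assert ss.scaffold_rmsd == pytest.approx(oracle_rmsd, abs=1e-8)
        # and the placed guest is actually on the host site
        placed = ss.base.molecules[0]
        d = placed.centroid - mol.centroid
        assert np.linalg.norm(cell.to_cart(d)) < 1.0

    def test_two_substitutions_bookkeeping(self, toy_beta4):
        sc = build_supercell(toy_beta4, (2, 1, 1))
        guest = guest_toy_template("hpx")
        ss = substitute(substitute(sc, 0, guest), 3, guest)
        assert (ss.N_g, ss.N_h) == (2, ss.N_cell - 2)

    def test_no_scaffold_is_incompatibility(self, toy_beta):
        bare = Molecule("host", ("C",), np.array([[0.5, 0.5, 0.5]]))
        s = CrystalStructure(toy_beta.cell, [bare], ["x,y,z"], 1)
        with pytest.raises(IncompatibilityError):
            substitute(s, 0, guest_toy_template())

    def test_reverse_substitution_restores_occupancy(self, toy_beta4):
        sc = build_supercell(toy_beta4, (2, 1, 1))
        pure = SolidSolutionSupercell.from_pure(sc)
        ss = substitute(pure, 2, guest_toy_template("hpx"))
        ss.base.molecules[2] = sc.molecules[2]
        ss.occupants[2] = pure.host_species
        assert ss.occupants == pure.occupants
        assert ss.N_g == 0


class TestKabsch:
    def test_recovers_random_rigid_motion(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(8, 3))
        R_true = Rotation.random(random_state=5).as_matrix()
        t_true = np.array([1.0, -2.0, 0.5])
        Q = P @ R_true.T + t_true
        R, t, rmsd = kabsch(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(R, R_true, atol=1e-10)
        assert np.allclose(t, t_true, atol=1e-10)


class TestMoleFraction:
    def test_one_in_36(self, toy_beta4):
        sc = build_supercell(toy_beta4, (3, 3, 1))
        ss = substitute(sc, 7, guest_toy_template())
        assert mole_fraction(ss).x_g == 1 / 36

    def test_endpoints_and_quarter(self, toy_beta4):
        sc = build_supercell(toy_beta4, (2, 1, 1))
        pure = SolidSolutionSupercell.from_pure(sc)
        assert mole_fraction(pure).x_g == 0.0
        ss = substitute(substitute(pure, 0, guest_toy_template()), 1,
                        guest_toy_template())
        assert mole_fraction(ss).x_g == 0.25


def oracle_orbit_count(n_sites, n_guest, repeats, z):
    """Independent translation-orbit counter: explicit orbit partition of
    all site combinations under the supercell translation group."""
    na, nb, nc = repeats

    def decode(s):
        m = s % z
        cell = s // z
        return cell // (nc * nb), (cell // nc) % nb, cell % nc, m

    def encode(i, j, k, m):
        return ((i * nb + j) * nc + k) * z + m

    orbits = set()
    for combo in itertools.combinations(range(n_sites), n_guest):
        orbit = frozenset(
            frozenset(encode((i + di) % na, (j + dj) % nb, (k + dk) % nc, m)
                      for i, j, k, m in map(decode, combo))
            for di in range(na) for dj in range(nb) for dk in range(nc))
        orbits.add(orbit)
    return len(orbits)


class TestEnsembles:
    def test_trivial_endpoints(self, toy_beta4):
        sc = build_supercell(toy_beta4, (2, 1, 1))
        guest = guest_toy_template()
        e0 = enumerate_configurations(sc, guest, 0)
        assert len(e0.members) == 1 and e0.members[0].N_g == 0
        efull = enumerate_configurations(sc, guest, sc.Z)
        assert len(efull.members) == 1 and efull.members[0].N_g == sc.Z

    def test_out_of_range_rejected(self, toy_beta4):
        sc = build_supercell(toy_beta4, (2, 1, 1))
        with pytest.raises(ArgumentError):
            enumerate_configurations(sc, guest_toy_template(), sc.Z + 1)

    @pytest.mark.parametrize("repeats,z,n_guest", [
        ((1, 1, 1), 4, 2),
        ((2, 1, 1), 2, 2),
        ((2, 2, 1), 2, 1),
        ((2, 2, 1), 2, 3),
        ((3, 1, 1), 2, 2),
    ])
    def test_pattern_count_matches_orbit_oracle(self, repeats, z, n_guest):
        n_sites = z * math.prod(repeats)
        got = enumerate_patterns(n_sites, n_guest, repeats, z)
        assert len(got) == oracle_orbit_count(n_sites, n_guest, repeats, z)
        # representatives are canonical and unique
        assert len({canonical_pattern(p, repeats, z) for p in got}) == len(got)

    def test_dedup_invariant_to_site_order(self):
        repeats, z = (2, 2, 1), 2
        n_sites = 8
        pats = enumerate_patterns(n_sites, 2, repeats, z)
        canon = {canonical_pattern(p, repeats, z) for p in pats}
        for combo in itertools.combinations(reversed(range(n_sites)), 2):
            assert canonical_pattern(tuple(sorted(combo)), repeats, z) in canon

    def test_members_share_stoichiometry(self, toy_beta4):
        sc = build_supercell(toy_beta4, (2, 1, 1))
        ens = enumerate_configurations(sc, guest_toy_template(), 2,
                                       max_members=16, seed=5)
        assert all(m.N_g == 2 and m.N_cell == 8 for m in ens.members)

    def test_axis_permutation_adds_swapped_cells(self, toy_beta4):
        sc = build_supercell(toy_beta4, (2, 1, 1))
        ens = enumerate_configurations(sc, guest_toy_template(), 1,
                                       permute_axes=True)
        tags = {p["cell"] for p in ens.provenance}
        assert tags == {"base", "ab-swap"}
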