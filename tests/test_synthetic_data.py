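import numpy as np
import pytest

from xtalloy.crystal_model import build_supercell, write_cif
from xtalloy.errors import ConfigError
from xtalloy.solid_solution import (
    SolidSolutionSupercell,
    enumerate_configurations,
    substitute,
)
from xtalloy.synthetic_data import (
    HPX_LIKE,
    IDENTITY_GUEST,
    TOLUENE,
    VACUUM,
    WATER,
    default_energy_model,
    guest_toy_template,
    make_interaction_table,
    make_toy_structure,
    per_guest_penalty,
    supercell_energy,
)
from xtalloy.thermo import lattice_energy_ss


class TestToyStructures:
    def test_beta_motif_contact_labels(self, vacuum_table):
        labels = {t.label for t in vacuum_table.types}
        assert labels == {"π-stack", "3H-bond", "2H-bond"}
        by_label = {}
        for t in vacuum_table.types:
            by_label[t.label] = by_label.get(t.label, 0) + t.multiplicity
        assert by_label["π-stack"] == 2
        assert by_label["3H-bond"] == 2
        assert by_label["2H-bond"] == 4

    def test_cubic_limit(self, toy_cubic):
        table = make_interaction_table(toy_cubic, VACUUM, cutoff=3.6)
        assert len(table.types) == 3

    def test_deterministic_cif_bytes(self):
        t1 = write_cif(make_toy_structure("beta"))
        t2 = write_cif(make_toy_structure("beta"))
        assert t1 == t2


class TestInteractionFixtures:
    def test_vacuum_identity_and_ordering(self, vacuum_table):
        dg = {t.label: t.dg_cryst for t in vacuum_table.types}
        for t in vacuum_table.types:
            assert t.dg_desolv == 0.0
            assert t.dg_cryst == t.dg_vacuum
        assert dg["3H-bond"] > dg["2H-bond"] > dg["π-stack"] > 0

    def test_water_strengthens_pi_and_weakens_hbonds(self, toy_beta,
                                                     vacuum_table,
                                                     water_table):
        vac = {t.label: t.dg_cryst for t in vacuum_table.types}
        wat = {t.label: t.dg_cryst for t in water_table.types}
        assert wat["π-stack"] > vac["π-stack"]
        assert wat["3H-bond"] < vac["3H-bond"]
        assert wat["2H-bond"] < vac["2H-bond"]
        assert wat["π-stack"] > max(wat["3H-bond"], wat["2H-bond"])

    def test_water_hpx_puts_3h_below_pi(self, toy_beta):
        table = make_interaction_table(toy_beta, WATER, HPX_LIKE)
        dg = {t.label: t.dg_cryst for t in table.types}
        assert dg["3H-bond"] < dg["π-stack"]

    def test_toluene_pi_prefers_to_dissolve(self, toy_beta):
        table = make_interaction_table(toy_beta, TOLUENE)
        dg = {t.label: t.dg_cryst for t in table.types}
        assert dg["π-stack"] < 0

    def test_identity_guest_changes_nothing(self, toy_beta, vacuum_table):
        table = make_interaction_table(toy_beta, VACUUM, IDENTITY_GUEST)
        for t1, t2 in zip(table.types, vacuum_table.types):
            assert t1.dg_cryst == pytest.approx(t2.dg_cryst)


class TestPairwiseEnergyModel:
    def test_extensivity(self, toy_beta4):
        model = default_energy_model()
        e_small = lattice_energy_ss(supercell_energy(
            model, SolidSolutionSupercell.from_pure(
                build_supercell(toy_beta4, (1, 1, 1)))))
        e_big = lattice_energy_ss(supercell_energy(
            model, SolidSolutionSupercell.from_pure(
                build_supercell(toy_beta4, (2, 1, 1)))))
        assert e_small == pytest.approx(e_big, rel=1e-12)

    def test_zero_wells_zero_energy(self, toy_beta4):
        model = default_energy_model()
        model.wells = {k: 0.0 for k in model.wells}
        model.penalties = {"hpx": {k: 0.0 for k in model.wells}}
        ss = SolidSolutionSupercell.from_pure(build_supercell(toy_beta4,
                                                              (1, 1, 1)))
        assert lattice_energy_ss(supercell_energy(model, ss)) == 0.0

    def test_unknown_species_rejected(self, toy_beta4):
        model = default_energy_model()
        ss = SolidSolutionSupercell.from_pure(build_supercell(toy_beta4,
                                                              (1, 1, 1)))
        ss.occupants[0] = "mystery"
        with pytest.raises(ConfigError):
            supercell_energy(model, ss)

    def test_guest_penalty_hand_sum_on_four_site_cell(self, toy_beta4):
        """One guest raises E_latt by its summed per-contact penalties:
        hand-sum over the toy contact graph (2 π + 2 3H + 4 2H)."""
        model = default_energy_model()
        sc = build_supercell(toy_beta4, (1, 1, 1))
        pure = SolidSolutionSupercell.from_pure(sc)
        doped = substitute(pure, 0, guest_toy_template("hpx"))
        de = (supercell_energy(model, doped).E_cell
              - supercell_energy(model, pure).E_cell)
        p = model.penalties["hpx"]
        hand = 2 * p["π-stack"] + 2 * p["3H-bond"] + 4 * p["2H-bond"]
        assert de == pytest.approx(hand, rel=1e-12)
        assert per_guest_penalty(model, "hpx", sc) == pytest.approx(hand)

    def test_energy_increases_with_guest_count(self, toy_beta4):
        model = default_energy_model()
        sc = build_supercell(toy_beta4, (2, 1, 1))
        guest = guest_toy_template("hpx")
        energies = []
        ss = SolidSolutionSupercell.from_pure(sc)
        for n, site in enumerate([0, 3, 5]):
            ss = substitute(ss, site, guest)
            energies.append(lattice_energy_ss(supercell_energy(model, ss)))
        assert energies == sorted(energies)

    def test_parameter_recovery_within_5pct(self, toy_beta4):
        """Fitting a line to E_latt(x) over 11 compositions recovers the
        injected per-guest penalty within 5%."""
        model = default_energy_model()
        sc = build_supercell(toy_beta4, (2, 2, 1))
        guest = guest_toy_template("xan")
        xs, es = [], []
        for n in range(0, 17, 2):
            ens = enumerate_configurations(sc, guest, n, max_members=4,
                                           seed=1)
            e = min(lattice_energy_ss(supercell_energy(model, m))
                    for m in ens.members)
            xs.append(n / sc.Z)
            es.append(e)
        slope = np.polyfit(xs, es, 1)[0]
        injected = per_guest_penalty(model, "xan", sc)
        assert slope == pytest.approx(injected, rel=0.05)

    def test_xan_slope_double_hpx(self, toy_beta4):
        model = default_energy_model()
        sc = build_supercell(toy_beta4, (1, 1, 1))
        assert per_guest_penalty(model, "xan", sc) == pytest.approx(
            2 * per_guest_penalty(model, "hpx", sc), rel=1e-12)
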