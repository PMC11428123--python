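import math

import numpy as np
import pytest

from xtalloy.errors import ArgumentError, ConfigError, MetricsUndefinedError
from xtalloy.growth import (
    GrowthConfig,
    GrowthSimulation,
    GrowthState,
    HEXAGONAL,
    KCAL_TO_KJ,
    identify_facets,
    morphology_metrics,
    run_growth,
    schedule_driving_force,
)
from xtalloy.synthetic_data import (
    VACUUM,
    make_interaction_table,
    make_toy_structure,
)

R_KJ = 8.314e-3


def quick_config(**kw):
    base = dict(total_iterations=20_000, dmu_relative=0.25,
                descent_start=19_000, equilibrium_iteration=19_500,
                box=(16, 12, 10), nucleus=(2, 2, 2), seed=3, log_every=0)
    base.update(kw)
    return GrowthConfig(**base)


class TestSchedule:
    def test_paper_defaults(self):
        cfg = GrowthConfig()
        assert schedule_driving_force(cfg, 0) == pytest.approx(
            100.0 * KCAL_TO_KJ)
        assert schedule_driving_force(cfg, 600_000) == 0.0
        assert schedule_driving_force(cfg, 1_000_000) == 0.0
        assert schedule_driving_force(cfg, 550_000) == pytest.approx(
            50.0 * KCAL_TO_KJ)

    def test_monotone_non_increasing(self):
        cfg = GrowthConfig()
        vals = [schedule_driving_force(cfg, it)
                for it in range(0, 1_000_001, 50_000)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert all(v >= 0 for v in vals)

    def test_out_of_range_iteration(self):
        with pytest.raises(ArgumentError):
            schedule_driving_force(GrowthConfig(), -1)

    def test_invalid_breakpoints(self):
        with pytest.raises(ConfigError):
            GrowthConfig(descent_start=700_000,
                         equilibrium_iteration=600_000)


class TestEngine:
    def test_empty_table_rejected(self, toy_beta, vacuum_table):
        from dataclasses import replace
        bad = replace(vacuum_table)
        bad.types = []
        with pytest.raises(ConfigError):
            GrowthSimulation(bad, toy_beta, quick_config())

    def test_seeded_determinism_and_divergence(self, toy_beta, vacuum_table):
        occ = [run_growth(vacuum_table, toy_beta,
                          quick_config(seed=9)).occupancy for _ in range(2)]
        assert np.array_equal(occ[0], occ[1])
        other = run_growth(vacuum_table, toy_beta,
                           quick_config(seed=10)).occupancy
        assert not np.array_equal(occ[0], other)

    @pytest.mark.parametrize("dmu_offset", [-4.0, -2.0, 0.0, 2.0, 4.0])
    def test_single_site_logistic_equilibrium(self, toy_beta, vacuum_table,
                                              dmu_offset):
        """Two-state site with frozen neighbors equilibrates to the
        analytic occupancy e^{βU'}/(1+e^{βU'}) within 3σ binomial error."""
        cfg = quick_config(equilibrium_mode="fixed_zero", seed=21)
        sim = GrowthSimulation(vacuum_table, toy_beta, cfg)
        site = (8, 6, 5, 0)
        for nb in sim.neighbors(*site):
            sim.occ[nb[:4]] = 1
        u = sim.site_energy(*site)
        dmu = -u + dmu_offset  # net bias = dmu_offset
        n = 40_000
        p = sim.single_site_occupancy(site, n, dmu=dmu)
        beta = 1.0 / (R_KJ * cfg.temperature)
        pred = 1.0 / (1.0 + math.exp(-beta * dmu_offset))
        # correlated samples: inflate the binomial σ by the chain's
        # integrated autocorrelation bound (conservative factor 5)
        sigma = math.sqrt(pred * (1 - pred) / n) * 5
        assert abs(p - pred) < 3 * sigma + 1e-3

    def test_connectivity_invariant_in_debug_mode(self, toy_beta,
                                                  vacuum_table):
        cfg = quick_config(total_iterations=3000, descent_start=2800,
                           equilibrium_iteration=2900, seed=4,
                           debug_check_connectivity=True)
        state = run_growth(vacuum_table, toy_beta, cfg)
        assert state.n_occupied > 0  # and no ConsistencyError raised

    def test_isotropic_interactions_give_isotropic_crystal(self, toy_cubic):
        """All-equal interactions on a cubic lattice: axis extents agree
        within 10% on average over seeded replicates."""
        table = make_interaction_table(toy_cubic, VACUUM, cutoff=3.6,
                                       wells={"π-stack": 8.0, "3H-bond": 8.0,
                                              "2H-bond": 8.0, "other": 8.0})
        ratios = []
        for seed in range(8):
            cfg = GrowthConfig(total_iterations=30_000, dmu_relative=0.3,
                               descent_start=29_000,
                               equilibrium_iteration=29_500,
                               box=(26, 26, 26), nucleus=(4, 4, 4),
                               seed=seed, log_every=0, max_sites=1500)
            state = run_growth(table, toy_cubic, cfg)
            rep = morphology_metrics(state, toy_cubic)
            e = sorted(rep.extents)
            ratios.append(e[2] / e[0])
        # kinetic roughness at ~1500 sites leaves a few % residual
        # anisotropy per replicate; the ensemble mean is close to 1
        assert np.mean(ratios) < 1.2
        assert max(ratios) < 1.4


class TestFacets:
    def test_perfect_cuboid_votes_100_family(self, toy_cubic):
        cfg = quick_config(box=(20, 20, 20))
        occ = np.zeros((20, 20, 20, 1), np.uint8)
        occ[5:15, 5:15, 5:15, 0] = 1
        state = GrowthState(toy_cubic, occ, cfg)
        areas = identify_facets(state, toy_cubic)
        fam100 = {(1, 0, 0), (0, 1, 0), (0, 0, 1)}
        top3 = {k for k, _ in sorted(areas.items(),
                                     key=lambda kv: -kv[1])[:3]}
        assert top3 == fam100
        assert sum(areas.get(f, 0.0) for f in fam100) > 0.40

    def test_plate_normal_is_thinnest_axis(self, toy_cubic):
        cfg = quick_config(box=(20, 20, 20))
        occ = np.zeros((20, 20, 20, 1), np.uint8)
        occ[9:11, 2:18, 2:18, 0] = 1  # plate thin along x (= a)
        state = GrowthState(toy_cubic, occ, cfg)
        areas = identify_facets(state, toy_cubic)
        assert max(areas, key=areas.get) == (1, 0, 0)

    def test_too_small_crystal_rejected(self, toy_cubic):
        cfg = quick_config(box=(8, 8, 8))
        occ = np.zeros((8, 8, 8, 1), np.uint8)
        occ[4, 4, 4, 0] = 1
        with pytest.raises(MetricsUndefinedError):
            identify_facets(GrowthState(toy_cubic, occ, cfg), toy_cubic)


class TestMorphologyMetrics:
    def test_single_unit_cell_extents(self, toy_cubic):
        cfg = quick_config(box=(8, 8, 8))
        occ = np.zeros((8, 8, 8, 1), np.uint8)
        occ[4, 4, 4, 0] = 1
        occ[4, 4, 5, 0] = 1
        occ[4, 5, 4, 0] = 1
        occ[5, 4, 4, 0] = 1
        rep = morphology_metrics(GrowthState(toy_cubic, occ, cfg), toy_cubic)
        a = toy_cubic.cell.a
        assert rep.extents == pytest.approx((2 * a, 2 * a, 2 * a), rel=1e-6)

    def test_constructed_hexagonal_prism(self, toy_cubic):
        """A hexagonal-prism occupancy is classified hexagonal."""
        cfg = quick_config(box=(24, 40, 40))
        occ = np.zeros((24, 40, 40, 1), np.uint8)
        cy = cz = 20.0
        for j in range(40):
            for k in range(40):
                # regular hexagon (flat-top) in the j-k plane
                y, z = j - cy, k - cz
                r = 14.0
                if (abs(z) <= r * math.sqrt(3) / 2
                        and abs(z + math.sqrt(3) * y) <= r * math.sqrt(3)
                        and abs(z - math.sqrt(3) * y) <= r * math.sqrt(3)):
                    occ[10:13, j, k, 0] = 1
        rep = morphology_metrics(GrowthState(toy_cubic, occ, cfg), toy_cubic)
        assert rep.cross_section == HEXAGONAL
        assert rep.habit == "plate"

    def test_degenerate_crystal_rejected(self, toy_cubic):
        cfg = quick_config(box=(8, 8, 8))
        occ = np.zeros((8, 8, 8, 1), np.uint8)
        occ[4, 4, 4, 0] = 1
        with pytest.raises(MetricsUndefinedError):
            morphology_metrics(GrowthState(toy_cubic, occ, cfg), toy_cubic)


class TestGrowthDissolutionBalance:
    def test_net_drift_statistically_zero_at_coexistence(self, toy_cubic):
        """A box-spanning bulk slab at the solubility-matched bias shows no
        systematic growth or dissolution over 10^5 cycles (two-sided sign
        test over replicates at alpha = 0.01)."""
        from scipy.stats import binomtest
        table = make_interaction_table(toy_cubic, VACUUM, cutoff=3.6,
                                       wells={"π-stack": 10.0,
                                              "3H-bond": 10.0,
                                              "2H-bond": 10.0,
                                              "other": 10.0})
        drifts = []
        for seed in range(8):
            cfg = GrowthConfig(total_iterations=100_000, dmu_initial=0.0,
                               descent_start=10, equilibrium_iteration=20,
                               box=(10, 10, 10), nucleus=(10, 10, 5),
                               seed=seed, log_every=20_000,
                               stop_at_wall=False)
            sim = GrowthSimulation(table, toy_cubic, cfg)
            state = sim.run()
            # drift measured from the first logged point (burn-in)
            burn = state.size_log[1][1]
            drifts.append(state.n_occupied - burn)
        nonzero = [d for d in drifts if d != 0]
        if nonzero:
            n_pos = sum(1 for d in nonzero if d > 0)
            assert binomtest(n_pos, len(nonzero), 0.5).pvalue > 0.01
        assert abs(np.mean(drifts)) < 0.02 * 500
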