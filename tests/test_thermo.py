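import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xtalloy.errors import ArgumentError, ConsistencyError
from xtalloy.solid_solution import Composition
from xtalloy.thermo import (
    EnergyAccounting,
    MixtureLine,
    R_GAS,
    STABLE,
    METASTABLE,
    INACCESSIBLE,
    accessibility_threshold,
    classify_stability,
    free_energy_curve,
    lattice_energy_ss,
    mixing_entropy,
    physical_mixture,
    vib_trendline,
)


class TestLatticeEnergy:
    @pytest.mark.parametrize("acct,expected", [
        (EnergyAccounting(-400, -90, 0, 4, 4, 0), -10.0),
        (EnergyAccounting(-390, -90, -80, 4, 3, 1), -10.0),
        (EnergyAccounting(-400, 0, 0, 4, 4, 0), -100.0),
    ])
    def test_hand_evaluated(self, acct, expected):
        assert lattice_energy_ss(acct) == pytest.approx(expected)

    def test_count_mismatch(self):
        with pytest.raises(ConsistencyError):
            lattice_energy_ss(EnergyAccounting(-400, -90, -80, 4, 3, 2))

    def test_invariant_under_replication(self):
        one = EnergyAccounting(-390, -90, -80, 4, 3, 1)
        two = EnergyAccounting(-780, -90, -80, 8, 6, 2)
        assert lattice_energy_ss(one) == pytest.approx(lattice_energy_ss(two))


class TestMixingEntropy:
    def test_closed_forms(self):
        assert mixing_entropy(0.5) == pytest.approx(R_GAS * math.log(2),
                                                    rel=1e-12)
        assert mixing_entropy(0.5) == pytest.approx(5.763, abs=5e-4)
        assert mixing_entropy(0.0) == 0.0
        assert mixing_entropy(1.0) == 0.0
        expected = -R_GAS * (0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert mixing_entropy(0.25) == pytest.approx(expected, rel=1e-12)
        assert mixing_entropy(0.25) == pytest.approx(4.675, abs=5e-4)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetric_nonnegative_peaked(self, x):
        s = mixing_entropy(x)
        assert s >= 0.0
        assert s == pytest.approx(mixing_entropy(1.0 - x), rel=1e-9,
                                  abs=1e-12)
        assert s <= R_GAS * math.log(2) + 1e-12

    def test_accepts_composition_objects(self):
        assert mixing_entropy(Composition(0.5)) == mixing_entropy(0.5)


class TestVibTrendline:
    def test_recovers_known_cubic(self):
        coeffs = (0.3, -0.7, 0.2, 0.9)  # a3 x^3 + a2 x^2 + a1 x + a0
        xs = [0.0, 0.25, 0.5, 0.75, 1.0]
        samples = [(x, np.polyval(coeffs, x)) for x in xs]
        poly = vib_trendline(samples)
        assert np.allclose(poly.coefficients, coeffs, atol=1e-9)

    def test_constant_samples(self):
        poly = vib_trendline([(x, 2.5) for x in (0, 0.3, 0.6, 1.0)])
        assert poly(0.17) == pytest.approx(2.5, abs=1e-9)

    def test_noisy_fit_matches_normal_equations(self):
        """Residuals equal those of an independently solved least-squares
        via the normal equations."""
        rng = np.random.default_rng(4)
        xs = np.linspace(0, 1, 9)
        ys = 1.0 - 2.0 * xs + 0.5 * xs ** 3 + rng.normal(0, 0.05, 9)
        poly = vib_trendline(zip(xs, ys))
        A = np.vander(xs, 4)
        beta = np.linalg.solve(A.T @ A, A.T @ ys)
        assert np.allclose(poly.coefficients, beta, atol=1e-8)

    def test_underdetermined_rejected(self):
        with pytest.raises(ArgumentError):
            vib_trendline([(0, 1), (0.5, 2), (1, 3)])


class TestFreeEnergyCurve:
    def test_reduces_to_lattice_energy_without_terms(self):
        pts = [(0.0, -10.0), (0.5, -8.0), (1.0, -6.0)]
        curve = free_energy_curve(pts, trendline=None, T=1e-9)
        assert np.allclose(curve.g, [-10, -8, -6], atol=1e-6)

    def test_mixing_term_value_at_half(self):
        curve = free_energy_curve([(0.0, 0.0), (0.5, 0.0)], None, T=300.0)
        assert curve.g[1] == pytest.approx(-300 * 5.763e-3, abs=2e-4)

    def test_entropy_lowers_g_in_the_interior(self):
        pts = [(x, -5.0) for x in (0.0, 0.25, 0.5, 0.75, 1.0)]
        curve = free_energy_curve(pts, None, T=300.0)
        assert np.all(curve.g[1:-1] < curve.e_latt[1:-1])
        assert curve.g[0] == curve.e_latt[0]

    def test_bad_temperature(self):
        with pytest.raises(ArgumentError):
            free_energy_curve([(0, 0), (1, 0)], None, T=-5)


class TestMixtureAndStability:
    def test_linear_interpolation(self):
        line = MixtureLine(-10.0, -6.0)
        assert physical_mixture(line, 0.0) == -10.0
        assert physical_mixture(line, 1.0) == -6.0
        assert physical_mixture(line, 0.5) == -8.0
        assert physical_mixture(line, 0.3) == pytest.approx(-8.8)

    def test_threshold_is_2rt(self):
        assert accessibility_threshold(300.0) == pytest.approx(4.9884,
                                                               abs=1e-3)

    @pytest.mark.parametrize("offset,expected", [
        (0.0, STABLE), (3.0, METASTABLE), (10.0, INACCESSIBLE)])
    def test_verdicts_by_offset(self, offset, expected):
        xs = (0.0, 0.25, 0.5)
        curve = free_energy_curve([(x, -10.0 + offset) for x in xs], None,
                                  T=300.0)
        # cancel the mixing term so the margin is exactly the offset
        curve.s_mix[:] = 0.0
        line = MixtureLine(-10.0, -10.0)
        verdicts = classify_stability(curve, line)
        assert all(v.verdict == expected for v in verdicts)
        assert all(v.margin == pytest.approx(offset) for v in verdicts)

    def test_energy_table_loading_with_unit_conversion(self, tmp_path):
        """A kcal/mol energy table converts to kJ/mol at parse time and
        reproduces the per-molecule lattice energies."""
        import pandas as pd
        from xtalloy.thermo import KCAL_TO_KJ, load_energy_table
        df = pd.DataFrame({
            "x_g": [0.0, 0.25], "E_cell": [-100.0, -95.0],
            "E_h_ref": [-20.0, -20.0], "E_g_ref": [-18.0, -18.0],
            "N_cell": [4, 4], "N_h": [4, 3], "N_g": [0, 1],
        })
        path = tmp_path / "e.csv"
        df.to_csv(path, index=False)
        pts = load_energy_table(path, units="kcal/mol")
        assert pts[0] == (0.0, pytest.approx((-100 + 80) / 4 * KCAL_TO_KJ))
        assert pts[1][1] == pytest.approx((-95 + 60 + 18) / 4 * KCAL_TO_KJ)

    def test_polymorph_gap_reporting(self):
        curve = free_energy_curve([(0.0, -10.0), (0.5, -10.0)], None, 300.0)
        curve.s_mix[:] = 0.0
        line = MixtureLine(-11.0, -11.0)
        verdicts = classify_stability(curve, line, polymorph_gap=1.5)
        assert [v.below_polymorph_gap for v in verdicts] == [True, True]
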