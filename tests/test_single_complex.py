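import numpy as np
import pytest

from quantalci.single_complex_model import (
    SingleComplexParams,
    VARIANTS,
    dub_effective_rate,
    growth_scale_factor,
    ode_rhs,
    simulate_single_complexes,
    steady_state_intensity,
    telegraph_occupancy,
)
from quantalci.trajectory_features import Trajectory, compute_descriptors

ALL_ONES = dict(kgrowth=1.0, klimit=1.0, kdbasal=1.0, kxbasal=1.0, kxdbasal=1.0)


class TestOdeRhs:
    def test_fresh_spot_growth_only(self):
        p = SingleComplexParams()
        dI, dX = ode_rhs(0.0, 0.0, 1, 1, p)
        assert dI == pytest.approx(p.kgrowth / p.klimit)
        assert dX == 0.0

    def test_unformed_spot_only_decays(self):
        p = SingleComplexParams()
        dI, _ = ode_rhs(2.0, 1.0, 0, 1, p)
        assert dI == pytest.approx(-p.kdbasal * 1.0 * 2.0)
        assert dI <= 0

    def test_unit_parameter_arithmetic(self):
        p = SingleComplexParams(**ALL_ONES)
        dI, dX = ode_rhs(1.0, 1.0, 1, 1, p)
        assert dI == pytest.approx(0.5 - 1.0)
        assert dX == pytest.approx(0.0)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            ode_rhs(-1.0, 0.0, 1, 1, SingleComplexParams())


class TestDubEffectiveRate:
    def test_reference_affinity(self):
        assert dub_effective_rate(1.0, 1.0) == pytest.approx(500.0 / 501.0)

    def test_tenfold_affinity(self):
        assert dub_effective_rate(1.0, 10.0) == pytest.approx(500.0 / 5001.0)

    def test_strictly_decreasing_in_affinity(self):
        affs = [1e-4, 1e-2, 0.1, 1.0, 10.0]
        rates = [dub_effective_rate(0.002, a) for a in affs]
        assert all(r0 > r1 for r0, r1 in zip(rates, rates[1:]))

    def test_invalid_affinity(self):
        with pytest.raises(ValueError):
            dub_effective_rate(1.0, 0.0)


class TestSteadyState:
    def test_all_ones_matches_independent_polynomial_root(self):
        # fixed point satisfies I^3 + I^2 - 1 = 0; root via numpy.roots
        roots = np.roots([1.0, 1.0, 0.0, -1.0])
        target = float(roots[(np.isreal(roots)) & (roots.real > 0)].real[0])
        got = steady_state_intensity(SingleComplexParams(**ALL_ONES))
        assert got == pytest.approx(target, abs=1e-10)
        assert got == pytest.approx(0.754878, abs=1e-6)

    def test_vanishing_growth_limit(self):
        p = SingleComplexParams(**{**ALL_ONES, "kgrowth": 1e-12})
        assert steady_state_intensity(p) < 1e-3

    def test_monotone_in_growth(self):
        lo = steady_state_intensity(SingleComplexParams(**ALL_ONES))
        hi = steady_state_intensity(SingleComplexParams(**{**ALL_ONES, "kgrowth": 2.0}))
        assert hi > lo

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            steady_state_intensity(SingleComplexParams(**{**ALL_ONES, "kdbasal": 0.0}))


class TestSimulation:
    def test_zero_growth_gives_zero_tracks(self):
        p = SingleComplexParams(kgrowth=0.0, n_spots=5, t_end=10.0)
        for tr in simulate_single_complexes(p):
            assert np.all(tr.intensity == 0.0)
            assert np.all(tr.xbasal == 0.0)

    def test_states_nonnegative_across_variants(self):
        for variant in VARIANTS:
            p = SingleComplexParams(variant=variant, affinity=0.05, n_spots=10,
                                    t_end=20.0, seed=3)
            for tr in simulate_single_complexes(p):
                assert np.all(tr.intensity >= 0.0)
                assert np.all(tr.xbasal >= 0.0)

    def test_intensity_zero_before_formation(self):
        p = SingleComplexParams(n_spots=10, spot_interval=2.0, t_end=30.0, seed=1)
        for tr in simulate_single_complexes(p):
            early = tr.times < tr.formation_time - 1e-9
            assert np.all(tr.intensity[early] == 0.0)

    def test_permanent_binding_equals_unit_growth_scale(self):
        """k_unbind_ref=0 keeps P_bound=1, matching growth_scale at factor 1."""
        base = dict(n_spots=6, t_end=15.0, seed=7)
        toggled = simulate_single_complexes(
            SingleComplexParams(variant="bound_toggle", k_unbind_ref=0.0, **base))
        scaled = simulate_single_complexes(
            SingleComplexParams(variant="growth_scale", growth_half_affinity=0.0,
                                **base))
        for a, b in zip(toggled, scaled):
            np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)

    def test_terminal_intensity_matches_fixed_point(self):
        p = SingleComplexParams(**ALL_ONES, variant="bound_toggle",
                                k_unbind_ref=0.0, n_spots=1, t_end=200.0,
                                dt=0.01, record_interval=10.0)
        terminal = simulate_single_complexes(p)[0].intensity[-1]
        expected = steady_state_intensity(p)
        assert terminal == pytest.approx(expected, rel=1e-4)

    def test_telegraph_occupancy_matches_equilibrium(self):
        p = SingleComplexParams(variant="bound_toggle", affinity=0.5,
                                n_spots=150, spot_interval=0.01, t_end=40.0,
                                seed=11)
        tracks = simulate_single_complexes(p)
        occ = np.mean([tr.bound[tr.times > tr.formation_time].mean()
                       for tr in tracks])
        expected = telegraph_occupancy(p.k_bind, p.k_unbind_ref / p.affinity)
        # Monte-Carlo tolerance: ~150 spots x ~10 switching cycles each
        assert occ == pytest.approx(expected, abs=0.03)

    def test_seeded_determinism(self):
        p = SingleComplexParams(n_spots=5, t_end=10.0, seed=42)
        a = simulate_single_complexes(p)
        b = simulate_single_complexes(p)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.intensity, y.intensity)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_mean_auc_decreases_with_affinity(self, variant):
        """Lower affinity monotonically reduces mean per-spot AUC."""
        aucs = []
        for aff in (1.0, 0.1, 0.01, 1e-4):
            p = SingleComplexParams(variant=variant, affinity=aff, n_spots=100,
                                    spot_interval=0.25, t_end=40.0, seed=5)
            tracks = simulate_single_complexes(p)
            aucs.append(np.mean([
                compute_descriptors(Trajectory(tr.times, tr.intensity)).auc
                for tr in tracks
            ]))
        assert all(hi > lo for hi, lo in zip(aucs, aucs[1:]))


def test_growth_scale_factor_bounds():
    assert growth_scale_factor(1.0, 0.0) == 1.0
    assert 0 < growth_scale_factor(0.01, 0.1) < growth_scale_factor(1.0, 0.1) < 1


def test_parameter_validation():
    with pytest.raises(ValueError):
        SingleComplexParams(affinity=0.0)
    with pytest.raises(ValueError):
        SingleComplexParams(variant="unknown")
    with pytest.raises(ValueError, match="dt too large"):
        SingleComplexParams(dt=2.0)
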