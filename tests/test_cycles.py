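"""Immigration cycles: closed forms, allele view, dilution times."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genedilution import cycles as cyc
from genedilution.genotypes import GenotypeDistribution, equilibrium_distribution

CHI_GRID = (0.005, 2.0 / 30.0, 0.2)


def _iterated(j, chi, delta_p00=1.0):
    """Explicit perturbation + relaxation composition (independent oracle)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cyc.iterate_cycles(j, chi, delta_p00)[-1]


class TestSingleCycle:
    def test_reference_delta_p_after_first_cycle(self):
        out = cyc.apply_cycle(GenotypeDistribution(1.0, 0.0, 0.0), 2.0 / 30.0)
        assert out.delta_p == pytest.approx(26.0 / 30.0)

    def test_zero_fraction_is_identity(self):
        d = equilibrium_distribution(0.3)
        out = cyc.apply_cycle(d, 0.0)
        assert out.as_array() == pytest.approx(d.as_array())

    def test_all_immigrant_fixed_point(self):
        d = GenotypeDistribution(0.0, 1.0, 0.0)
        out = cyc.apply_cycle(d, 0.3)
        assert (out.p_n, out.p_s, out.p_ns) == pytest.approx((0.0, 1.0, 0.0))

    def test_total_probability_conserved(self):
        d = GenotypeDistribution(0.3, 0.2, 0.5)
        out = cyc.apply_cycle(d, 0.123)
        assert out.p_n + out.p_s + out.p_ns == pytest.approx(1.0, abs=1e-12)

    def test_chi_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cyc.apply_cycle(GenotypeDistribution(1, 0, 0), 1.0)


class TestClosedForms:
    @pytest.mark.parametrize("chi", CHI_GRID)
    def test_delta_p_closed_form_matches_iteration(self, chi):
        dp = 1.0
        for j in range(51):
            assert cyc.delta_p_after_cycles(j, chi) == pytest.approx(dp, abs=1e-12)
            dp = dp * (1.0 - chi) - chi

    @pytest.mark.parametrize("chi", CHI_GRID)
    def test_subgroup_closed_form_matches_explicit_composition(self, chi):
        for j in (0, 1, 2, 5, 10, 25, 50):
            closed = cyc.subgroup_probs_after_cycles(j, chi).as_array()
            iterated = _iterated(j, chi).as_array()
            np.testing.assert_allclose(closed, iterated, atol=1e-12, rtol=0)

    def test_reference_values(self):
        assert cyc.delta_p_after_cycles(10, 2 / 30) == pytest.approx(
            2 * (28 / 30) ** 10 - 1
        )
        assert cyc.subgroup_probs_after_cycles(10, 2 / 30).p_n == pytest.approx(
            0.2516144, abs=1e-6
        )
        assert cyc.delta_p_after_cycles(0, 0.1, 0.25) == 0.25

    def test_limits(self):
        assert cyc.subgroup_probs_after_cycles(0, 0.05).as_array() == pytest.approx(
            (1.0, 0.0, 0.0)
        )
        far = cyc.subgroup_probs_after_cycles(5000, 0.05)
        assert (far.p_n, far.p_s) == pytest.approx((0.0, 1.0), abs=1e-12)
        assert cyc.delta_p_after_cycles(5000, 0.05) == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("chi", CHI_GRID)
    def test_monotonicity_in_cycle_number(self, chi):
        p_n = [cyc.subgroup_probs_after_cycles(j, chi).p_n for j in range(40)]
        p_s = [cyc.subgroup_probs_after_cycles(j, chi).p_s for j in range(40)]
        p_ns = [cyc.subgroup_probs_after_cycles(j, chi).p_ns for j in range(40)]
        assert np.all(np.diff(p_n) < 0)
        assert np.all(np.diff(p_s) > 0)
        # heterozygotes rise then fall: one sign change in the difference
        signs = np.sign(np.diff(p_ns))
        changes = np.count_nonzero(np.diff(signs[signs != 0]))
        assert changes <= 1


class TestAlleleFrequencies:
    @pytest.mark.parametrize("chi", CHI_GRID)
    @pytest.mark.parametrize("j", [0, 1, 3, 10, 50])
    def test_continent_island_equivalence(self, j, chi):
        # q from the genotype closed forms equals the classical recursion
        p, q = cyc.allele_frequencies(j, chi)
        d = cyc.subgroup_probs_after_cycles(j, chi)
        assert p + q == pytest.approx(1.0, abs=1e-15)
        assert q == pytest.approx((1.0 - chi) ** j, abs=1e-15)
        assert q == pytest.approx(d.allele_freq_resident, abs=1e-12)
        assert p == pytest.approx(d.allele_freq_immigrant, abs=1e-12)

    def test_reference_points(self):
        assert cyc.allele_frequencies(0, 0.3) == pytest.approx((0.0, 1.0))
        assert cyc.allele_frequencies(1, 0.5) == pytest.approx((0.5, 0.5))


class TestDilutionTime:
    def test_single_cycle_target(self):
        chi = 0.25
        assert cyc.cycles_to_target(chi**2, chi) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "chi,expected", [(2.0 / 30.0, 76.7588), (0.02, 262.1336)]
    )
    def test_reference_cycle_counts(self, chi, expected):
        j_f = cyc.cycles_to_target(0.990, chi)
        assert j_f == pytest.approx(expected, abs=1e-3)
        # bracketing oracle: ceil(J_f) is the smallest j achieving the target
        j_int = cyc.whole_cycles_to_target(0.990, chi)
        assert cyc.subgroup_probs_after_cycles(j_int, chi).p_s >= 0.990
        assert cyc.subgroup_probs_after_cycles(j_int - 1, chi).p_s < 0.990

    def test_reference_total_time(self):
        assert cyc.total_time(0.990, 0.02, 100.0) == pytest.approx(26213.36, abs=0.5)

    def test_total_time_linear_in_interval(self):
        assert cyc.total_time(0.99, 0.05, 200.0) == pytest.approx(
            2.0 * cyc.total_time(0.99, 0.05, 100.0)
        )

    def test_total_time_decreasing_in_chi(self):
        chis = np.linspace(0.005, 0.5, 60)
        t_f = [cyc.total_time(0.99, c, 100.0) for c in chis]
        assert np.all(np.diff(t_f) < 0)

    def test_replacement_limit(self):
        assert cyc.total_time(0.99, 0.999, 100.0) < 150.0

    def test_degenerate_targets_rejected(self):
        for bad in (0.0, 1.0):
            with pytest.raises(ValueError):
                cyc.cycles_to_target(bad, 0.05)


class TestInverseProblem:
    @settings(derandomize=True, max_examples=100)
    @given(
        p_sf=st.floats(0.5, 0.9999),
        chi=st.floats(0.001, 0.5),
        delta_t=st.floats(10.0, 500.0),
    )
    def test_round_trip_with_total_time(self, p_sf, chi, delta_t):
        t_f = cyc.total_time(p_sf, chi, delta_t)
        chi_back = cyc.chi_for_time(p_sf, delta_t, t_f)
        assert chi_back == pytest.approx(chi, rel=1e-9)

    def test_single_cycle_limit(self):
        p_sf = 0.99
        assert cyc.chi_for_time(p_sf, 100.0, 100.0) == pytest.approx(
            1.0 - (1.0 - math.sqrt(p_sf))
        )

    def test_reference_inversion(self):
        assert cyc.chi_for_time(0.990, 50.0, 30000.0) == pytest.approx(0.0088, abs=2e-4)


class TestSchedule:
    def test_small_perturbation_advisory(self):
        with pytest.warns(UserWarning, match="small-perturbation"):
            cyc.CycleSchedule(chi=0.2, delta_t=100.0)

    def test_relaxation_advisory(self):
        s = cyc.CycleSchedule(chi=0.05, delta_t=40.0)
        with pytest.warns(UserWarning, match="re-equilibrate"):
            assert not s.check_relaxation(tau_e=24.0)
        assert s.check_relaxation(tau_e=10.0)

    def test_helpers_delegate_to_closed_forms(self):
        s = cyc.CycleSchedule(chi=0.02, delta_t=100.0)
        assert s.time_for(0.990) == pytest.approx(cyc.total_time(0.990, 0.02, 100.0))
        assert s.cycles_for(0.990) == pytest.approx(cyc.cycles_to_target(0.990, 0.02))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            cyc.CycleSchedule(chi=0.0, delta_t=100.0)
        with pytest.raises(ValueError):
            cyc.CycleSchedule(chi=0.05, delta_t=0.0)
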