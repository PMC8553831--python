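"""Unit and property tests for the trait-based rate functions.

The closed forms (kernel, overlap integral) are checked against scipy
adaptive quadrature as the independent oracle; allometric and power-law
behaviour against hand arithmetic.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from evoweb import (
    CommunityState,
    Parameters,
    Species,
    attack_matrix,
    attack_rate,
    competition_coefficient,
    competition_matrix,
    competition_overlap,
    consumption_rate,
    feeding_kernel,
    handling_time,
    max_attack_rate,
    metabolic_loss,
)

SQRT_2PI = math.sqrt(2 * math.pi)

# positive trait strategies kept in ranges the simulation actually visits
trait_m = st.floats(1.0, 1e6)
trait_f = st.floats(1e-3, 1e6)
trait_s = st.floats(0.3, 5.0)


def _sp(m, f, s, sid=0):
    return Species(id=sid, m=m, f=f, s=s, origin="ancestor")


class TestFeedingKernel:
    def test_peak_at_feeding_centre(self):
        assert feeding_kernel(1.0, 0.4, 1.0) == pytest.approx(1 / (0.4 * SQRT_2PI))
        assert feeding_kernel(1.0, 0.4, 1.0) == pytest.approx(0.99736, abs=5e-6)

    def test_symmetric_in_log_mass(self):
        for delta in (0.1, 0.7, 2.3):
            lo = feeding_kernel(100.0, 0.5, 10 ** (2 - delta))
            hi = feeding_kernel(100.0, 0.5, 10 ** (2 + delta))
            assert lo == pytest.approx(hi, rel=1e-12)

    @pytest.mark.parametrize("f,s,m", [(0, 0.4, 1), (1, 0, 1), (1, 0.4, 0), (-1, 0.4, 1)])
    def test_rejects_non_positive_arguments(self, f, s, m):
        with pytest.raises(ValueError):
            feeding_kernel(f, s, m)

    @given(f=trait_f, s=trait_s)
    @settings(max_examples=30, deadline=None)
    def test_normalised_over_log_mass(self, f, s):
        total, _ = quad(lambda u: feeding_kernel(f, s, 10.0 ** u),
                        math.log10(f) - 12 * s, math.log10(f) + 12 * s)
        assert total == pytest.approx(1.0, abs=1e-8)

    @given(f=trait_f, s=trait_s, m=trait_m)
    @settings(max_examples=50, deadline=None)
    def test_positive_and_peak_bounded(self, f, s, m):
        val = feeding_kernel(f, s, m)
        assert 0 < val <= 1 / (s * SQRT_2PI) * (1 + 1e-12)


class TestAttackRate:
    def test_ancestor_on_basal_resource(self, ancestor, params):
        # 100^0.75 * kernel peak at the basal mass
        assert attack_rate(ancestor, 1.0, params) == pytest.approx(31.54, abs=0.005)

    def test_unit_mass_consumer_reduces_to_kernel(self, params):
        sp = _sp(1.0, 5.0, 0.35)
        assert attack_rate(sp, 5.0, params) == pytest.approx(1 / (0.35 * SQRT_2PI))

    def test_power_law_in_body_mass(self, params):
        a1 = attack_rate(_sp(10.0, 1.0, 0.4), 1.0, params)
        a2 = attack_rate(_sp(20.0, 1.0, 0.4), 1.0, params)
        assert a2 / a1 == pytest.approx(2 ** 0.75, rel=1e-12)

    def test_max_attack_rate_is_attack_at_centre(self, params):
        sp = _sp(37.0, 4.2, 0.61)
        assert max_attack_rate(sp, params) == pytest.approx(
            attack_rate(sp, sp.f, params), rel=1e-12)

    def test_ancestor_max_attack_value(self, ancestor, params):
        assert max_attack_rate(ancestor, params) == pytest.approx(31.54, abs=0.005)

    def test_wider_range_lowers_peak(self, params):
        peaks = [max_attack_rate(_sp(50.0, 2.0, s), params) for s in (0.3, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(peaks, peaks[1:]))

    @given(f=trait_f, s=trait_s, m=trait_m, mj=trait_m)
    @settings(max_examples=50, deadline=None)
    def test_ratio_to_max_is_log_gaussian(self, f, s, m, mj):
        sp = _sp(m, f, s)
        p = Parameters()
        ratio = attack_rate(sp, mj, p) / max_attack_rate(sp, p)
        d = math.log10(f) - math.log10(mj)
        assert 0 < ratio <= 1 + 1e-12
        assert ratio == pytest.approx(math.exp(-d * d / (2 * s * s)), rel=1e-9)


class TestAllometricRates:
    # the printed coefficient/exponent arithmetic, with the exponent explicit
    printed = Parameters(h_exp=-0.25)

    @pytest.mark.parametrize("m,h,x", [(1.0, 0.4, 0.3), (16.0, 0.2, 0.15)])
    def test_quarter_power_arithmetic(self, m, h, x):
        assert handling_time(m, self.printed) == pytest.approx(h, rel=1e-12)
        assert metabolic_loss(m, self.printed) == pytest.approx(x, rel=1e-12)

    def test_strictly_decreasing_in_mass(self, params):
        ms = [1.0, 2.0, 10.0, 1e3, 1e6]
        hs = [handling_time(m, params) for m in ms]
        xs = [metabolic_loss(m, params) for m in ms]
        assert all(a > b for a, b in zip(hs, hs[1:]))
        assert all(a > b for a, b in zip(xs, xs[1:]))

    def test_saturated_intake_to_metabolism_ratio_mass_independent(self, params):
        """With the default exponents the best-case energy balance
        e/(m h) / x is the same at every body mass, so viability does not
        impose a body-size ceiling (the m=100 ancestor must be viable)."""
        def ratio(m):
            return params.e / (m * handling_time(m, params)) / metabolic_loss(m, params)
        r0 = ratio(1.0)
        assert r0 > 1  # saturated consumers can pay their metabolism
        for m in (10.0, 100.0, 1e4, 1e8):
            assert ratio(m) == pytest.approx(r0, rel=1e-12)

    def test_rejects_non_positive_mass(self, params):
        with pytest.raises(ValueError):
            handling_time(0.0, params)
        with pytest.raises(ValueError):
            metabolic_loss(-1.0, params)


class TestConsumptionRate:
    def test_zero_biomass_collapses_denominator(self, ancestor, params):
        state = CommunityState(0.0, 0.0, [ancestor], np.array([0.0]))
        g = consumption_rate(ancestor, 0, state, params)
        assert g == pytest.approx(attack_rate(ancestor, 1.0, params) / ancestor.m)

    def test_type_ii_saturation_limit(self, params):
        sp = _sp(10.0, 1.0, 0.4)
        state = CommunityState(0.0, 1e12, [sp], np.array([0.0]))
        g = consumption_rate(sp, 0, state, params)
        # g * B0 -> 1/(m h) as prey biomass diverges
        assert g * 1e12 == pytest.approx(
            1.0 / (sp.m * handling_time(sp.m, params)), rel=1e-6)

    def test_brute_force_arithmetic(self, ancestor, params):
        state = CommunityState(0.0, 2.0, [ancestor], np.array([1.5]))
        # independent scalar assembly of Holling II over both prey items
        a0 = attack_rate(ancestor, 1.0, params)
        a_self = attack_rate(ancestor, ancestor.m, params)
        h = handling_time(ancestor.m, params)
        expected = a0 / (ancestor.m * (1 + h * (a0 * 2.0 + a_self * 1.5)))
        assert consumption_rate(ancestor, 0, state, params) == pytest.approx(
            expected, rel=1e-12)

    def test_out_of_range_resource_index(self, ancestor, params):
        state = CommunityState(0.0, 2.0, [ancestor], np.array([1.0]))
        with pytest.raises(ValueError):
            consumption_rate(ancestor, 2, state, params)

    def test_cannibalism_switch_excludes_self(self, ancestor):
        p = Parameters(include_cannibalism=False)
        state = CommunityState(0.0, 2.0, [ancestor], np.array([1.0]))
        assert consumption_rate(ancestor, 1, state, p) == 0.0


class TestCompetition:
    def test_self_overlap_closed_form(self):
        sp = _sp(10.0, 3.0, 0.4)
        assert competition_overlap(sp, sp) == pytest.approx(1 / (2 * 0.4 * math.sqrt(math.pi)))
        assert competition_overlap(sp, sp) == pytest.approx(0.7052, abs=5e-5)

    def test_vanishes_for_distant_feeding_centres(self):
        a, b = _sp(10, 1.0, 0.4, 1), _sp(10, 1e12, 0.4, 2)
        assert competition_overlap(a, b) < 1e-90

    def test_symmetric(self, rng):
        for _ in range(20):
            a = _sp(rng.uniform(1, 100), 10 ** rng.uniform(-2, 4), rng.uniform(0.3, 3), 1)
            b = _sp(rng.uniform(1, 100), 10 ** rng.uniform(-2, 4), rng.uniform(0.3, 3), 2)
            assert competition_overlap(a, b) == pytest.approx(
                competition_overlap(b, a), rel=1e-14)

    def test_closed_form_matches_quadrature(self, rng):
        for _ in range(20):
            a = _sp(rng.uniform(1, 100), 10 ** rng.uniform(-2, 4), rng.uniform(0.3, 3), 1)
            b = _sp(rng.uniform(1, 100), 10 ** rng.uniform(-2, 4), rng.uniform(0.3, 3), 2)
            lo = min(math.log10(a.f) - 15 * a.s, math.log10(b.f) - 15 * b.s)
            hi = max(math.log10(a.f) + 15 * a.s, math.log10(b.f) + 15 * b.s)
            numeric, _ = quad(
                lambda u: feeding_kernel(a.f, a.s, 10 ** u) * feeding_kernel(b.f, b.s, 10 ** u),
                lo, hi, limit=200)
            assert competition_overlap(a, b) == pytest.approx(numeric, rel=1e-8)

    def test_identical_kernels_give_c0(self, params):
        a, b = _sp(10, 2.0, 0.5, 1), _sp(99, 2.0, 0.5, 2)  # m does not enter
        assert competition_coefficient(a, b, params) == pytest.approx(params.c0)

    def test_asymmetric_closed_form(self, params):
        a, b = _sp(10, 2.0, 0.3, 1), _sp(10, 2.0, 0.6, 2)
        expected = 0.05 * (1 / math.sqrt(2 * math.pi * (0.09 + 0.36))) / (1 / (2 * 0.3 * math.sqrt(math.pi)))
        assert competition_coefficient(a, b, params) == pytest.approx(expected, rel=1e-12)
        assert competition_coefficient(a, b, params) != pytest.approx(
            competition_coefficient(b, a, params))

    def test_self_competition_is_contract_violation(self, params):
        sp = _sp(10, 2.0, 0.5, 7)
        with pytest.raises(ValueError):
            competition_coefficient(sp, sp, params)


class TestMatrixForms:
    """The vectorised matrices must agree entry-wise with the scalar ops."""

    def _community(self, rng, n=6):
        sps = [_sp(rng.uniform(1, 1e3), 10 ** rng.uniform(-1, 3),
                   rng.uniform(0.3, 2), sid=i) for i in range(n)]
        return sps

    def test_attack_matrix_matches_scalar(self, rng, params):
        sps = self._community(rng)
        A = attack_matrix(sps, params)
        assert A.shape == (6, 7)
        for i, sp in enumerate(sps):
            assert A[i, 0] == pytest.approx(attack_rate(sp, params.m0, params), rel=1e-12)
            for j, prey in enumerate(sps):
                assert A[i, j + 1] == pytest.approx(
                    attack_rate(sp, prey.m, params), rel=1e-12)

    def test_competition_matrix_matches_scalar(self, rng, params):
        sps = self._community(rng)
        C = competition_matrix(sps, params)
        assert np.all(np.diag(C) == 0)
        for i in range(len(sps)):
            for j in range(len(sps)):
                if i != j:
                    assert C[i, j] == pytest.approx(
                        competition_coefficient(sps[i], sps[j], params), rel=1e-12)

    def test_empty_community(self, params):
        assert attack_matrix([], params).shape == (0, 1)
        assert competition_matrix([], params).shape == (0, 0)


class TestDomainTypes:
    def test_parameters_validation(self):
        with pytest.raises(ValueError):
            Parameters(e=-0.1)
        with pytest.raises(ValueError):
            Parameters(p=1.5)
        with pytest.warns(UserWarning):
            Parameters(z_invader=0.05)  # below the mutant SD

    def test_species_validation(self):
        with pytest.raises(ValueError):
            Species(id=0, m=-1, f=1, s=0.4)
        with pytest.raises(ValueError):
            Species(id=0, m=1, f=1, s=0.4, birth_time=100.0, death_time=50.0)
        sp = Species(id=0, m=1, f=1, s=0.4, birth_time=100.0, death_time=300.0)
        assert sp.lifespan == 200.0

    def test_state_validation(self):
        with pytest.raises(ValueError):
            CommunityState(0.0, 1.0, [_sp(1, 1, 0.4)], np.array([]))
        with pytest.raises(ValueError):
            CommunityState(0.0, float("nan"), [], np.array([]))
        with pytest.raises(ValueError):
            CommunityState(0.0, 1.0, [_sp(1, 1, 0.4)], np.array([-0.5]))
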