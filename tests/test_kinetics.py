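"""Model space, translocation rates, equilibrium constants, propensities."""

import math

import numpy as np
import pytest

from ratchetabc.constants import DELTA_ANGSTROM, KBT_J, PN_ANGSTROM_J
from ratchetabc.energetics import EnergyLandscape
from ratchetabc.kinetics import (
    MODEL_PRIOR,
    MODEL_SPACE,
    Condition,
    ParameterSet,
    analytic_velocity,
    model_network,
    propensity_table,
    sequence_averaged_Ktau,
    translocation_equilibrium,
    translocation_rates,
)
from ratchetabc.simulator import build_site_rates
from ratchetabc.synthetic_data import random_template


def flat_landscape(n=20, pre=0.0, post=0.0, ts=0.0, l0=13):
    c = lambda v: np.full(n, float(v))
    return EnergyLandscape(np.arange(l0, l0 + n), c(pre), c(post), c(ts), l0, l0 + n)


class TestTranslocationRates:
    def test_zero_exponent_gives_prefactor(self):
        ls = flat_landscape()
        p = ParameterSet(k_cat=1, K_D=1, dG_tdag=0.0)
        kf, _ = translocation_rates(15, p, Condition.make(0.0, 100.0), ls)
        assert kf == pytest.approx(1e6)

    def test_barrier_shift_scales_both_rates(self):
        ls = flat_landscape(pre=-1.0, post=0.5, ts=2.0)
        cond = Condition.make(3.0, 100.0)
        p0 = ParameterSet(k_cat=1, K_D=1, dG_t1=-1.0, delta1=1.2, dG_tdag=4.0)
        p1 = ParameterSet(k_cat=1, K_D=1, dG_t1=-1.0, delta1=1.2, dG_tdag=5.0)
        r0 = translocation_rates(15, p0, cond, ls)
        r1 = translocation_rates(15, p1, cond, ls)
        assert r1[0] / r0[0] == pytest.approx(math.exp(-1), rel=1e-12)
        assert r1[1] / r0[1] == pytest.approx(math.exp(-1), rel=1e-12)

    def test_force_work_of_one_kBT_multiplies_forward_rate_by_e(self):
        # F * delta1 = k_B T  <=>  F = kBT / (delta1 * 1e-22 J/(pN*A))
        ls = flat_landscape()
        delta1 = 1.7
        force = KBT_J / (delta1 * PN_ANGSTROM_J)
        p = ParameterSet(k_cat=1, K_D=1, delta1=delta1, dG_tdag=2.0)
        kf0, _ = translocation_rates(15, p, Condition.make(0.0, 1.0), ls)
        kf1, _ = translocation_rates(15, p, Condition.make(force, 1.0), ls)
        assert kf1 / kf0 == pytest.approx(math.e, rel=1e-9)
        assert force == pytest.approx(25.176, rel=1e-3)

    @pytest.mark.parametrize("force", [-8.0, 0.0, 12.0])
    @pytest.mark.parametrize("dG_tdag,delta1", [(3.0, 0.6), (7.0, 3.0)])
    def test_detailed_balance(self, landscape, force, dG_tdag, delta1):
        # k_fwd/k_bck = exp(F*delta/kBT) / K_tau, independent of the barrier
        p = ParameterSet(
            k_cat=10, K_D=10, dG_t1=-1.3, delta1=delta1, dG_tdag=dG_tdag
        )
        cond = Condition.make(force, 100.0)
        for l in (13, 40, 90):
            kf, kb = translocation_rates(l, p, cond, landscape)
            K = translocation_equilibrium(l, p, cond, landscape)
            fdelta = force * DELTA_ANGSTROM * PN_ANGSTROM_J / KBT_J
            assert kf / kb == pytest.approx(math.exp(fdelta) / K, rel=1e-10)

    def test_non_finite_energy_rejected(self):
        ls = flat_landscape()
        ls.dG_pre[2] = np.nan
        p = ParameterSet(k_cat=1, K_D=1)
        with pytest.raises(ValueError, match="non-finite"):
            translocation_rates(15, p, Condition.make(0, 1.0), ls)


class TestTranslocationEquilibrium:
    def test_symmetric_landscape(self):
        ls = flat_landscape(pre=1.0, post=1.0)
        p = ParameterSet(k_cat=1, K_D=1, dG_t1=0.0)
        assert translocation_equilibrium(15, p, Condition.make(0, 1), ls) == 1.0

    def test_direct_evaluation(self):
        # dG_pre - dG_post = -1 and dG_t1 = -2 gives K_tau = e^{-1}
        ls = flat_landscape(pre=0.0, post=1.0)
        p = ParameterSet(k_cat=1, K_D=1, dG_t1=-2.0)
        K = translocation_equilibrium(15, p, Condition.make(0, 1), ls)
        assert K == pytest.approx(math.exp(-1), rel=1e-12)


class TestAnalyticVelocity:
    def test_saturating_ntp_limit(self):
        p = ParameterSet(k_cat=24.7, K_D=15.6)
        assert analytic_velocity(p, 1.0, 0.0, 1e12) == pytest.approx(24.7, rel=1e-6)

    def test_reference_point(self):
        # half-saturation at 2*K_D with K_tau = 1 halves k_cat
        p = ParameterSet(k_cat=24.7, K_D=15.6)
        assert analytic_velocity(p, 1.0, 0.0, 31.2) == pytest.approx(12.35)

    def test_strong_assisting_force_limit(self):
        p = ParameterSet(k_cat=20.0, K_D=10.0)
        v = analytic_velocity(p, 5.0, 1e4, 10.0)
        assert v == pytest.approx(20.0 / (1 + 10.0 / 10.0), rel=1e-6)

    def test_zero_ntp(self):
        p = ParameterSet(k_cat=20.0, K_D=10.0)
        assert analytic_velocity(p, 1.0, 0.0, 0.0) == 0.0

    def test_monotone_in_force_and_ntp(self):
        p = ParameterSet(k_cat=20.0, K_D=10.0)
        forces = np.linspace(-10, 30, 9)
        v_f = [analytic_velocity(p, 1.0, f, 50.0) for f in forces]
        assert np.all(np.diff(v_f) > 0)
        ntps = np.logspace(0, 3.3, 8)
        v_n = [analytic_velocity(p, 1.0, 5.0, n) for n in ntps]
        assert np.all(np.diff(v_n) > 0)
        assert max(v_f + v_n) < p.k_cat


class TestSequenceAveragedKtau:
    def test_homogeneous_landscape(self):
        ls = flat_landscape(pre=0.3, post=0.8)
        p = ParameterSet(k_cat=1, K_D=1, dG_t1=0.0)
        expected = math.exp(-(0.3 - 0.8))
        assert sequence_averaged_Ktau(p, ls) == pytest.approx(expected, rel=1e-12)

    def test_two_site_geometric_mean(self):
        ls = flat_landscape(n=2)
        # ratios e and 1/e: ln K = +-1
        ls.dG_pre[:] = [1.0, -1.0]
        p = ParameterSet(k_cat=1, K_D=1)
        assert sequence_averaged_Ktau(p, ls) == pytest.approx(1.0, rel=1e-12)

    def test_dG_t1_shift_multiplies_by_exponential(self, landscape):
        pa = ParameterSet(k_cat=1, K_D=1, dG_t1=-2.0)
        pb = ParameterSet(k_cat=1, K_D=1, dG_t1=-4.6)
        ka = sequence_averaged_Ktau(pa, landscape)
        kb = sequence_averaged_Ktau(pb, landscape)
        assert ka / kb == pytest.approx(math.exp(2.6), rel=1e-9)


class TestModelSpace:
    def test_parameter_counts(self):
        counts = {m: MODEL_SPACE[m].n_parameters for m in MODEL_SPACE}
        assert counts == {
            1: 2, 2: 3, 3: 3, 4: 3, 5: 4, 6: 4, 7: 4, 8: 4,
            9: 5, 10: 5, 11: 5, 12: 6,
        }

    def test_translocation_equilibrium_models_never_use_delta1(self):
        for m in (1, 2, 4, 5):
            spec = MODEL_SPACE[m]
            assert spec.translocation_equilibrium
            assert "delta1" not in spec.active_parameters
            assert "dG_tdag" not in spec.active_parameters

    def test_pinned_models(self):
        assert set(MODEL_SPACE[1].active_parameters) == {"k_cat", "K_D"}
        assert set(MODEL_SPACE[5].active_parameters) == {
            "k_cat", "K_D", "k_bind", "dG_t1",
        }
        assert set(MODEL_SPACE[11].active_parameters) == {
            "k_cat", "K_D", "dG_t1", "delta1", "dG_tdag",
        }
        assert set(MODEL_SPACE[12].active_parameters) == set(
            ("k_cat", "K_D", "k_bind", "dG_t1", "delta1", "dG_tdag")
        )

    def test_prior_masses(self):
        assert sum(MODEL_PRIOR.values()) == pytest.approx(1.0)
        for m, mass in MODEL_PRIOR.items():
            expected = 2 / 16 if m in (1, 2, 4, 5) else 1 / 16
            assert mass == expected


class TestModelNetwork:
    def test_symmetric_no_self_edges(self):
        net = model_network()
        for i, nbrs in net.items():
            assert i not in nbrs
            for j in nbrs:
                assert i in net[j]

    def test_edges_differ_by_one_parameter(self):
        net = model_network()
        for i, nbrs in net.items():
            for j in nbrs:
                diff = set(MODEL_SPACE[i].active_parameters) ^ set(
                    MODEL_SPACE[j].active_parameters
                )
                assert len(diff) == 1

    def test_model_1_degree_and_model_12_neighbours(self):
        net = model_network()
        assert len(net[1]) >= 2
        assert 2 in net[1] and 4 in net[1]
        # neighbours of the full model are exactly the 5-parameter models
        assert set(net[12]) == {
            m for m in MODEL_SPACE if MODEL_SPACE[m].n_parameters == 5
        }


class TestPropensities:
    def test_pretranslocated_has_single_outbound_reaction(self, landscape):
        p = ParameterSet(k_cat=10, K_D=10, k_bind=1, dG_tdag=5.0)
        rxns = propensity_table(
            (40, 0, False), MODEL_SPACE[12], p, Condition.make(0, 100.0),
            landscape, "A",
        )
        assert len(rxns) == 1
        assert rxns[0].label == "forward"
        assert rxns[0].successor == (40, 1, False)

    def test_zero_ntp_zeroes_binding_and_catalysis(self, landscape):
        p = ParameterSet(k_cat=10, K_D=10, k_bind=1, dG_tdag=5.0)
        cond = Condition.make(0, 0.0)
        bound_rxns = propensity_table(
            (40, 1, False), MODEL_SPACE[12], p, cond, landscape, "A"
        )
        binding = [r for r in bound_rxns if r.label == "binding"]
        assert binding[0].rate == 0.0
        coalesced = propensity_table(
            (40, 1, False), MODEL_SPACE[1], p, cond, landscape, "A"
        )
        assert coalesced[0].rate == 0.0

    def test_binding_equilibrium_occupancy(self, landscape):
        # K_D = [NTP] puts half the coalesced state in the bound form
        p = ParameterSet(k_cat=50, K_D=10, dG_t1=-1.0, delta1=1.0, dG_tdag=5.0)
        rxns = propensity_table(
            (40, 1, False), MODEL_SPACE[11], p, Condition.make(0, 10.0),
            landscape, "A",
        )
        cat = [r for r in rxns if r.label == "catalysis"][0]
        assert cat.rate == pytest.approx(25.0)

    def test_coalesced_flux_conservation(self, landscape):
        # total outbound of the binding-equilibrium state equals the
        # occupancy-weighted sum of the kinetic model's outbound rates
        p = ParameterSet(k_cat=35, K_D=12, k_bind=0.7, dG_t1=-1.0,
                         delta1=1.0, dG_tdag=5.0)
        cond = Condition.make(4.0, 30.0)
        f = 30.0 / (30.0 + p.K_D)
        kin = propensity_table((40, 1, False), MODEL_SPACE[12], p, cond,
                               landscape, "G")
        k_bck = [r.rate for r in kin if r.label == "backward"][0]
        coal = propensity_table((40, 1, False), MODEL_SPACE[11], p, cond,
                                landscape, "G")
        total = sum(r.rate for r in coal)
        assert total == pytest.approx((1 - f) * k_bck + f * p.k_cat, rel=1e-10)

    def test_no_backtracking_successors(self, landscape):
        p = ParameterSet(k_cat=10, K_D=10, k_bind=1, dG_tdag=5.0)
        for state in [(40, 0, False), (40, 1, False), (40, 1, True)]:
            for m in (1, 5, 11, 12):
                for r in propensity_table(
                    state, MODEL_SPACE[m], p, Condition.make(-5, 50.0),
                    landscape, "C",
                ):
                    l, t, _ = r.successor
                    assert t in (0, 1)
                    assert l >= state[0]


class TestSubmodelNesting:
    def test_neutral_values_reproduce_submodel_rates(self, template, landscape):
        # model 12 with dG_t1 = 0 and delta1 = delta/2 equals model 7
        cond = Condition.make(8.0, 200.0)
        full = ParameterSet(
            k_cat=30, K_D=20, k_bind=0.5, dG_t1=0.0,
            delta1=DELTA_ANGSTROM / 2, dG_tdag=5.0,
        )
        r12 = build_site_rates(template, MODEL_SPACE[12], full, cond, landscape)
        r7 = build_site_rates(template, MODEL_SPACE[7], full, cond, landscape)
        for a, b in zip(
            (r12.r01, r12.r10, r12.r12, r12.r21, r12.r1a, r12.r2a),
            (r7.r01, r7.r10, r7.r12, r7.r21, r7.r1a, r7.r2a),
        ):
            np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_inactive_parameters_are_neutralised(self, template, landscape):
        # a submodel ignores whatever value is carried in an inactive slot
        cond = Condition.make(8.0, 200.0)
        a = ParameterSet(k_cat=30, K_D=20, k_bind=0.5, dG_t1=-3.0,
                         delta1=1.0, dG_tdag=5.0)
        b = ParameterSet(k_cat=30, K_D=20, k_bind=0.5, dG_t1=2.0,
                         delta1=3.0, dG_tdag=5.0)
        ra = build_site_rates(template, MODEL_SPACE[7], a, cond, landscape)
        rb = build_site_rates(template, MODEL_SPACE[7], b, cond, landscape)
        np.testing.assert_allclose(ra.r01, rb.r01, rtol=1e-12)
        np.testing.assert_allclose(ra.r10, rb.r10, rtol=1e-12)


class TestParameterSet:
    def test_positivity_and_delta1_bounds(self):
        with pytest.raises(ValueError):
            ParameterSet(k_cat=-1, K_D=1)
        with pytest.raises(ValueError):
            ParameterSet(k_cat=1, K_D=1, delta1=3.4)

    def test_k_rel_is_derived(self):
        p = ParameterSet(k_cat=1, K_D=15.0, k_bind=0.2)
        assert p.k_rel == pytest.approx(3.0)

    def test_vector_round_trip(self):
        p = ParameterSet(k_cat=3, K_D=4, k_bind=5, dG_t1=-6, delta1=1.0, dG_tdag=8)
        assert ParameterSet.from_vector(p.as_vector()) == p
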