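"""Tests for the equilibrium solver and the in-silico study generator."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dmcycle as d
from dmcycle.itc import ITCIsothermFit
from dmcycle.nmr import dynamic_range_check, exchange_constant
from dmcycle.synthetic import (
    FIG5_TITRATION_POINTS_mM,
    child_rng,
    competitive_equilibrium_solve,
    generate_competition_titration,
    generate_itc_dataset,
    generate_study,
    true_binding_network,
)


def newton_2guest_oracle(Ht, G1, G2, K1, K2):
    """Independent 1-D Newton iteration on free host, written from scratch."""
    H = Ht / 2.0
    for _ in range(400):
        f = H + K1 * H * G1 / (1 + K1 * H) + K2 * H * G2 / (1 + K2 * H) - Ht
        fp = 1 + K1 * G1 / (1 + K1 * H) ** 2 + K2 * G2 / (1 + K2 * H) ** 2
        step = f / fp
        H = max(H - step, 1e-30)
        if abs(step) < 1e-25:
            break
    return H


class TestCompetitiveEquilibrium:
    def test_weak_binding_linear_regime(self):
        Ht, Gt, K = 1e-6, 1e-6, 10.0  # K·Ht ≪ 1
        eq = competitive_equilibrium_solve(Ht, [Gt], [K])
        assert eq.bound[0] == pytest.approx(K * Ht * Gt, rel=1e-3)

    def test_symmetric_guests_bind_equally(self):
        eq = competitive_equilibrium_solve(3e-4, [5e-4, 5e-4], [1e6, 1e6])
        assert eq.bound[0] == pytest.approx(eq.bound[1], rel=1e-12)

    def test_matches_independent_newton_oracle(self):
        # five-spectrum titration mid-point concentrations: 0.30 mM host,
        # 0.46 / 1.20 mM guests, K = 10⁸ / 10⁷
        Ht, G1, G2 = 0.30e-3, 0.46e-3, 1.20e-3
        K1, K2 = 1e8, 1e7
        eq = competitive_equilibrium_solve(Ht, [G1, G2], [K1, K2])
        H = newton_2guest_oracle(Ht, G1, G2, K1, K2)
        assert eq.free_host == pytest.approx(H, rel=1e-9)
        assert eq.bound[0] == pytest.approx(K1 * H * G1 / (1 + K1 * H), rel=1e-9)
        assert eq.bound[1] == pytest.approx(K2 * H * G2 / (1 + K2 * H), rel=1e-9)

    @given(
        st.floats(min_value=-5, max_value=-2),  # log10 host total (M)
        st.floats(min_value=-5, max_value=-2),
        st.floats(min_value=-5, max_value=-2),
        st.floats(min_value=2, max_value=11),  # log10 K
        st.floats(min_value=2, max_value=11),
    )
    @settings(max_examples=80, deadline=None)
    def test_mass_conservation(self, lh, lg1, lg2, lk1, lk2):
        Ht, G = 10.0**lh, [10.0**lg1, 10.0**lg2]
        eq = competitive_equilibrium_solve(Ht, G, [10.0**lk1, 10.0**lk2])
        assert eq.mass_balance_residual(Ht, G) < 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            competitive_equilibrium_solve(1e-4, [1e-4], [0.0])
        with pytest.raises(ValueError):
            competitive_equilibrium_solve(-1e-4, [1e-4], [1e6])


class TestDeterminism:
    def test_same_seed_same_bytes(self, scenario_factory):
        sc = scenario_factory(seed=5)
        net = true_binding_network(sc)
        key = ("B", "H", "water")
        _, h1 = generate_itc_dataset(sc, key, net)
        _, h2 = generate_itc_dataset(sc, key, net)
        assert h1.tobytes() == h2.tobytes()

    def test_artefacts_draw_independently(self, scenario_factory):
        """Generating one dataset never perturbs another (child-seed split)."""
        sc = scenario_factory(seed=5)
        net = true_binding_network(sc)
        _, before = generate_itc_dataset(sc, ("B", "H", "water"), net)
        generate_itc_dataset(sc, ("B", "Me", "water"), net)  # interleaved
        _, after = generate_itc_dataset(sc, ("B", "H", "water"), net)
        assert np.array_equal(before, after)

    def test_study_reproducible(self, scenario_factory):
        a = generate_study(scenario_factory(seed=3), route="direct")
        b = generate_study(scenario_factory(seed=3), route="direct")
        for key in a.measurements:
            assert a.measurements[key].K.value == b.measurements[key].K.value

    def test_child_rng_labels_distinct(self):
        assert child_rng(1, "a").normal() != child_rng(1, "b").normal()


class TestItcGeneration:
    def test_noise_free_recovery(self, noiseless_scenario):
        net = true_binding_network(noiseless_scenario)
        key = ("C", "", "water")
        sched, heats = generate_itc_dataset(noiseless_scenario, key, net)
        est = ITCIsothermFit(constrain_n=True).fit(sched, heats)
        assert est.K_.value == pytest.approx(net[key].K, rel=1e-4)
        assert est.dH_.value == pytest.approx(net[key].dH, rel=1e-4)

    def test_tight_binder_yields_step_and_flag(self, noiseless_scenario):
        # aqueous A complex with a nitro guest: ΔG ≈ −66 kJ/mol, far
        # beyond the measurable window at the default programme
        net = true_binding_network(noiseless_scenario)
        key = ("A", "NO2", "water")
        assert net[key].dG < -60.0
        sched, heats = generate_itc_dataset(
            noiseless_scenario, key, net, auto_range=False
        )
        est = ITCIsothermFit(constrain_n=True).fit(sched, heats)
        assert not est.K_reliable_
        assert est.dH_.value == pytest.approx(net[key].dH, rel=0.02)

    def test_auto_ranging_brings_c_into_window(self, noiseless_scenario):
        net = true_binding_network(noiseless_scenario)
        key = ("D", "", "water")  # weak: c ≈ 1 at the default programme
        sched, _ = generate_itc_dataset(noiseless_scenario, key, net)
        c = net[key].K * sched.host_cell_concentration
        assert 1.0 <= c <= 1e4


class TestCompetitionGeneration:
    def test_zero_noise_round_trip(self, noiseless_scenario):
        net = true_binding_network(noiseless_scenario)
        pair = (("A", "H", "water"), ("A", "Me", "water"))
        obs = generate_competition_titration(
            noiseless_scenario, "1", pair, network=net
        )
        truth = net[pair[1]].K / net[pair[0]].K
        for o in obs:
            assert exchange_constant(o) == pytest.approx(truth, rel=1e-6)

    def test_extreme_ratio_rejected_at_fixed_concentrations(
        self, noiseless_scenario
    ):
        # a 10³ affinity gap at the fixed five-point programme leaves the
        # minor complex invisible
        net = dict(true_binding_network(noiseless_scenario))
        pair = (("A", "H", "water"), ("A", "NO2", "water"))
        ratio = net[pair[1]].K / net[pair[0]].K
        assert ratio > 1e3
        obs = generate_competition_titration(
            noiseless_scenario,
            "1",
            pair,
            points_mM=[p for p in FIG5_TITRATION_POINTS_mM if p[2] > 0],
            network=net,
        )
        assert not any(dynamic_range_check(o)[0] for o in obs)

    def test_noisy_ratio_recovery(self, scenario_factory):
        """2 % integral noise: the per-edge estimate stays within 3 sd."""
        sc = scenario_factory(seed=23)
        net = true_binding_network(sc)
        pair = (("A", "H", "water"), ("A", "Me", "water"))
        truth = math.log10(net[pair[1]].K / net[pair[0]].K)
        hits = 0
        for rep in range(60):
            sc_r = scenario_factory(seed=3000 + rep)
            obs = generate_competition_titration(sc_r, "1", pair, network=net)
            logs = [math.log10(exchange_constant(o)) for o in obs]
            sd = np.std(logs, ddof=1)
            hits += abs(np.mean(logs) - truth) <= 3 * max(sd, 1e-4)
        assert hits >= 0.95 * 60


class TestStudyGeneration:
    def test_zero_noise_dmc_returns_injected_terms_exactly(
        self, noiseless_scenario
    ):
        study = generate_study(noiseless_scenario, route="direct")
        for (X, solvent), truth in study.interaction_truth.items():
            dd = d.dmc_delta(study.quad(X, solvent), "G")
            assert dd.value == pytest.approx(truth, abs=1e-9)

    def test_zero_noise_hammett_is_exact(self, noiseless_scenario, usable_params):
        study = generate_study(noiseless_scenario, route="direct")
        fit = d.hammett_fit(
            [
                (usable_params[X].sigma_m, d.dmc_delta(study.quad(X, "chloroform"), "G").value)
                for X in usable_params
            ]
        )
        assert fit.slope == pytest.approx(-11.7, abs=1e-9)
        assert fit.intercept == pytest.approx(-7.4, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_instrument_route_recovers_interactions(self, scenario_factory):
        sc = scenario_factory(seed=7, interaction_noise_sd=0.0)
        study = generate_study(sc, route="instrument")
        for (X, solvent), truth in study.interaction_truth.items():
            dd = d.dmc_delta(study.quad(X, solvent), "G")
            assert dd.value == pytest.approx(truth, abs=3.0 * max(dd.sigma, 0.3))

    def test_measurement_methods_mirror_tightness_split(self, scenario_factory):
        """Tight A-type complexes go through the NMR ladder, the rest ITC."""
        sc = scenario_factory(seed=11)
        study = generate_study(sc, route="instrument")
        methods = {k: m.method for k, m in study.measurements.items()}
        assert all(
            methods[k] == "ITC" for k in methods if k[0] in ("B", "C", "D")
        )
        water_A = [k for k in methods if k[0] == "A" and k[2] == "water"]
        assert water_A
        assert all(methods[k] == "NMR-competition" for k in water_A)

    def test_itc_nmr_cross_validation(self, scenario_factory):
        """Complexes measurable by both routes give K estimates that agree
        within joint 95 % intervals."""
        # a host with weaker side-wall interactions, so that even the
        # aryl-guest complex stays inside the calorimetric window
        sc = scenario_factory(
            seed=31,
            solvents=("chloroform",),
            host_terms={("chloroform", "full"): -19.5, ("chloroform", "mutant"): -15.0},
        )
        net = true_binding_network(sc)
        key_lo, key_hi = ("C", "", "chloroform"), ("A", "H", "chloroform")
        assert net[key_hi].K * 0.04e-3 < 1e4  # ITC-measurable
        # ITC estimates
        ests = {}
        for key in (key_lo, key_hi):
            sched, heats = generate_itc_dataset(sc, key, net)
            ests[key] = ITCIsothermFit(constrain_n=True).fit(sched, heats)
        # NMR competition between the two guests on the shared host
        obs = generate_competition_titration(sc, "2", (key_lo, key_hi), network=net)
        logs = [math.log10(exchange_constant(o)) for o in obs]
        lo = ests[key_lo]
        nmr_logK = math.log10(lo.K_.value) + np.mean(logs)
        nmr_sig = math.hypot(
            lo.K_.sigma / (lo.K_.value * math.log(10)),
            np.std(logs, ddof=1),
        )
        hi = ests[key_hi]
        itc_logK = math.log10(hi.K_.value)
        itc_sig = hi.K_.sigma / (hi.K_.value * math.log(10))
        assert abs(nmr_logK - itc_logK) <= 1.96 * math.hypot(nmr_sig, itc_sig)
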