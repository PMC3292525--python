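import numpy as np
import pytest

from brute_force import brute_isotopologues, brute_rhs, brute_simulate
from labeldyn._builder import toy_chain_scheme
from labeldyn.experiments import ExperimentSpec, TracerSpec, condition_a
from labeldyn.isodynamics import (
    IsotopomerEngine,
    isotopomer_rhs,
    observables,
    simulate_labeling,
    to_isotopologues,
)
from labeldyn.network import AtomMap, NetworkScheme, Pool, Reaction


def _condensation_scheme():
    """A 3-pool toy with a condensation, a split and a scrambled transfer."""
    pools = {
        "A": Pool("A", 2, "cytosol", 1.0),
        "B": Pool("B", 1, "cytosol", 0.8),
        "C": Pool("C", 3, "cytosol", 0.5),
    }
    rxns = {
        "cond": Reaction(
            "cond",
            (("A", "A"), ("B", "B")),
            (("C", "C"),),
            AtomMap.single(
                [(("A", 1), ("C", 1)), (("A", 2), ("C", 2)), (("B", 1), ("C", 3))]
            ),
            {"law": "mass_action", "params": ["k_cond"]},
        ),
        "split": Reaction(
            "split",
            (("C", "C"),),
            (("A", "A"), ("B", "B")),
            AtomMap.single(
                [(("C", 1), ("A", 1)), (("C", 2), ("A", 2)), (("C", 3), ("B", 1))]
            ),
            {"law": "mass_action", "params": ["k_split"]},
        ),
        "scram": Reaction(
            "scram",
            (("C", "C"),),
            (("C2", "C"),),
            AtomMap.scrambled(
                [
                    (0.5, [(("C", c), ("C2", c)) for c in (1, 2, 3)], []),
                    (0.5, [(("C", c), ("C2", 4 - c)) for c in (1, 2, 3)], []),
                ]
            ),
            {"law": "mass_action", "params": ["k_scram"]},
            kind="exchange",
        ),
    }
    return NetworkScheme("toy", pools, rxns)


class TestIsotopomerRhs:
    def test_no_reactions_gives_zero_derivative(self):
        scheme = NetworkScheme("t", {"X": Pool("X", 2, "cytosol", 1.0)}, {})
        eng = IsotopomerEngine(scheme)
        x = np.array([0.4, 0.1, 0.3, 0.2])
        assert np.all(isotopomer_rhs(eng, np.zeros(0), x) == 0.0)

    def test_identity_transfer_moves_pattern_unchanged(self):
        toy = toy_chain_scheme(2)
        eng = IsotopomerEngine(toy)
        x = np.zeros(eng.n_states)
        x[eng.offsets["X1"] + 0b11] = 1.0  # X1 entirely doubly labeled
        x[eng.offsets["X2"] + 0] = 0.5
        flux = np.array([0.3])
        dx = eng.rhs(x, flux)
        assert dx[eng.offsets["X2"] + 0b11] == pytest.approx(0.3)
        assert dx[eng.offsets["X1"] + 0b11] == pytest.approx(-0.3)
        others = [
            i for i in range(eng.n_states)
            if i not in (eng.offsets["X1"] + 0b11, eng.offsets["X2"] + 0b11)
        ]
        assert np.all(dx[others] == 0.0)

    def test_condensation_of_half_labeled_with_unlabeled(self):
        scheme = _condensation_scheme()
        eng = IsotopomerEngine(scheme)
        x = np.zeros(eng.n_states)
        oA, oB, oC = eng.offsets["A"], eng.offsets["B"], eng.offsets["C"]
        x[oA + 0b01] = 0.5  # A: 50% labeled at C1
        x[oA + 0b00] = 0.5
        x[oB + 0] = 1.0  # B unlabeled
        x[oC + 0] = 0.5
        flux = np.array([2.0, 0.0, 0.0])  # cond only
        dx = eng.rhs(x, flux)
        # product C carries A's C1 label, B contributes an unlabeled C3
        assert dx[oC + 0b001] == pytest.approx(2.0 * 0.5)
        assert dx[oC + 0b000] == pytest.approx(2.0 * 0.5 - 0.0)
        assert dx[oC + 0b100] == 0.0

    def test_matches_brute_force_at_random_states(self):
        scheme = _condensation_scheme()
        eng = IsotopomerEngine(scheme)
        rng = np.random.default_rng(5)
        flux_vec = rng.uniform(0.1, 1.0, len(eng.reaction_ids))
        flux_map = dict(zip(eng.reaction_ids, flux_vec))
        for _ in range(5):
            x = rng.uniform(0.01, 1.0, eng.n_states)
            state = {
                p: {i: x[eng.offsets[p] + i] for i in range(eng.sizes[p])}
                for p in eng.pool_ids
            }
            d_brute = brute_rhs(scheme, flux_map, state)
            dx = eng.rhs(x, flux_vec)
            for p in eng.pool_ids:
                for i in range(eng.sizes[p]):
                    assert dx[eng.offsets[p] + i] == pytest.approx(
                        d_brute[p][i], abs=1e-12
                    )

    def test_jacobian_matches_finite_differences(self, engine_b):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.01, 1.0, engine_b.n_states)
        flux = rng.uniform(0.0, 1e-2, len(engine_b.reaction_ids))
        J = engine_b.jacobian(x, flux)
        h = 1e-7
        cols = rng.choice(engine_b.n_states, size=40, replace=False)
        for k in cols:
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            col = (engine_b.rhs(xp, flux) - engine_b.rhs(xm, flux)) / (2 * h)
            assert np.allclose(J[:, k], col, atol=1e-6)


class TestBruteForceEquivalence:
    def test_toy_network_time_course(self):
        """Production integrator vs naive enumeration on the 3-pool toy."""
        scheme = _condensation_scheme()
        eng = IsotopomerEngine(scheme)
        # condensation and split balanced so pool totals stay constant
        flux_map = {"cond": 0.25, "split": 0.25, "scram": 0.4}
        flux_vec = np.array([flux_map[r] for r in eng.reaction_ids])
        x0 = np.zeros(eng.n_states)
        x0[eng.offsets["A"] + 0b01] = 0.6
        x0[eng.offsets["A"] + 0b00] = 0.4
        x0[eng.offsets["B"] + 0b1] = 0.3
        x0[eng.offsets["B"] + 0b0] = 0.5
        x0[eng.offsets["C"] + 0] = 0.5
        state0 = {
            p: {i: x0[eng.offsets[p] + i] for i in range(eng.sizes[p])}
            for p in eng.pool_ids
        }
        t_eval = np.linspace(0, 4.0, 5)
        ref = brute_simulate(scheme, flux_map, state0, (0, 4.0), t_eval)

        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda t, x: eng.rhs(x, flux_vec),
            (0, 4.0), x0, method="BDF",
            jac=lambda t, x: eng.jacobian(x, flux_vec),
            rtol=1e-10, atol=1e-12, t_eval=t_eval,
        )
        assert sol.success
        assert np.allclose(sol.y, ref.y, atol=1e-6)

    def test_label_conserved_without_release_reactions(self):
        scheme = _condensation_scheme()
        eng = IsotopomerEngine(scheme)
        rng = np.random.default_rng(2)
        flux_vec = rng.uniform(0.05, 0.5, len(eng.reaction_ids))
        x0 = rng.uniform(0.0, 0.5, eng.n_states)

        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda t, x: eng.rhs(x, flux_vec), (0, 5.0), x0,
            method="BDF", jac=lambda t, x: eng.jacobian(x, flux_vec),
            rtol=1e-10, atol=1e-12,
        )
        labels = [eng.total_label(sol.y[:, i]) for i in range(sol.y.shape[1])]
        assert np.allclose(labels, labels[0], rtol=1e-8)


class TestToIsotopologues:
    def test_label_outside_fragment_counts_as_m0(self):
        vec = np.zeros(64)
        vec[0b000011] = 1.0  # carbons 1 and 2 labeled
        dist = to_isotopologues(vec, "glc", "C3-C6")
        assert dist.m(0) == pytest.approx(1.0)

    def test_label_inside_fragment_counted(self):
        vec = np.zeros(64)
        vec[0b000011] = 1.0
        dist = to_isotopologues(vec, "glc", "C1-C4")
        assert dist.m(2) == pytest.approx(1.0)

    def test_matches_popcount_brute_force(self):
        rng = np.random.default_rng(9)
        vec = rng.uniform(0, 1, 64)
        for lo, hi in [(1, 6), (1, 4), (3, 6), (2, 5)]:
            dist = to_isotopologues(vec, "glc", (lo, hi))
            ref = brute_isotopologues(vec, lo, hi)
            assert np.allclose(dist.fractions, ref, atol=1e-12)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            to_isotopologues(np.zeros(8), "x")

    def test_bad_fragment_rejected(self):
        with pytest.raises(ValueError):
            to_isotopologues(np.ones(8), "x", (1, 5))


class TestSimulateLabeling:
    def test_tracer_initialization(self, scheme_b, params_b, engine_b):
        eng = engine_b
        x0 = eng.initial_state(condition_a(), {"glc_med": 20.0})
        glc = eng.pool_state(x0, "glc_med")
        assert glc[0b000011] == pytest.approx(10.0)
        assert glc[0] == pytest.approx(10.0)
        assert glc.sum() == pytest.approx(20.0)
        # everything intracellular starts unlabeled
        hexp = eng.pool_state(x0, "hexP")
        assert hexp[0] == hexp.sum()

    def test_zero_flux_state_constant(self, scheme_b, params_b):
        zero = params_b.updated({k: 0.0 for k in params_b.values})
        sim = simulate_labeling(scheme_b, zero, condition_a())
        assert np.allclose(sim.states[-1], sim.states[0], atol=1e-12)
        obs = observables(sim)
        assert obs[("glucose", "C1-C6", "m0")] == pytest.approx(0.5, abs=1e-9)
        assert obs[("glucose", "C1-C6", "m2")] == pytest.approx(0.5, abs=1e-9)
        assert obs[("lactate", "C1-C3", "m0")] == pytest.approx(1.0)

    def test_single_pool_wash_in_closed_form(self):
        """Constant labeled influx: labeled fraction follows 1 − e^(−vt/X)."""
        pools = {
            "G": Pool("G", 1, "medium", 100.0),
            "X": Pool("X", 1, "cytosol", 0.5),
            "Y": Pool("Y", 1, "cytosol", 0.01),
        }
        rxns = {
            "in": Reaction(
                "in", (("G", "G"),), (("X", "X"),),
                AtomMap.single([(("G", 1), ("X", 1))]),
                {"law": "mass_action", "params": ["k_in"]},
            ),
            "out": Reaction(
                "out", (("X", "X"),), (("Y", "Y"),),
                AtomMap.single([(("X", 1), ("Y", 1))]),
                {"law": "mass_action", "params": ["k_out"]},
            ),
        }
        scheme = NetworkScheme("washin", pools, rxns)
        v = 0.05
        params = {"k_in": v / 100.0, "k_out": v / 0.5}
        exp = ExperimentSpec(
            id="wash", duration=20.0, medium={},
            tracers=(TracerSpec("G", 1, 1.0),),
        )
        sim = simulate_labeling(
            scheme, params, exp, t_eval=np.linspace(0, 20, 11), rtol=1e-9
        )
        X0 = 0.5
        for i, t in enumerate(sim.times):
            xs = sim.engine.pool_state(sim.states[i], "X")
            labeled = xs[1] / xs.sum()
            assert labeled == pytest.approx(1 - np.exp(-v * t / X0), abs=2e-3)

    def test_pool_sums_track_kinetic_totals(self, sim_b_precise):
        sim = sim_b_precise
        for i, t in enumerate(sim.times):
            sums = sim.engine.pool_totals(sim.states[i])
            kin = sim.totals.conc_at(t)
            for j, pid in enumerate(sim.totals.pool_ids):
                if pid in sums:
                    assert sums[pid] == pytest.approx(
                        kin[j], rel=1e-6, abs=1e-12
                    )

    def test_repeated_runs_bit_identical(self, scheme_b, params_b, engine_b):
        kw = dict(engine=engine_b, t_eval=np.array([0.0, 120.0]))
        s1 = simulate_labeling(scheme_b, params_b, condition_a(), **kw)
        s2 = simulate_labeling(scheme_b, params_b, condition_a(), **kw)
        assert np.array_equal(s1.states, s2.states)

    def test_pool_order_invariance(self, scheme_b, params_b):
        from labeldyn.network import scheme_from_dict, scheme_to_dict

        obj = scheme_to_dict(scheme_b)
        obj["pools"] = obj["pools"][::-1]
        reordered = scheme_from_dict(obj)
        kw = dict(t_eval=np.array([0.0, 120.0]), rtol=1e-8, atol=1e-12)
        s1 = simulate_labeling(scheme_b, params_b, condition_a(), **kw)
        s2 = simulate_labeling(reordered, params_b, condition_a(), **kw)
        o1 = observables(s1)
        o2 = observables(s2)
        for key, val in o1.items():
            assert o2[key] == pytest.approx(val, abs=1e-7)


class TestObservables:
    def test_distributions_sum_to_one(self, sim_b_precise):
        obs = observables(sim_b_precise)
        groups = {}
        for (met, frag, qty), val in obs.items():
            if qty != "conc":
                groups.setdefault((met, frag), 0.0)
                groups[(met, frag)] += val
        for key, total in groups.items():
            assert total == pytest.approx(1.0, abs=1e-9), key

    def test_glycogen_fragments_consistent_with_whole_molecule(self, sim_b_precise):
        """Fragment distributions marginalize the deposited isotopomers."""
        x = sim_b_precise.state_at_end()
        eng = sim_b_precise.engine
        vec = eng.pool_state(x, "glycogen")
        whole = to_isotopologues(vec, "glycogen")
        for frag in ("C1-C4", "C3-C6"):
            dist = to_isotopologues(vec, "glycogen", frag)
            ref = brute_isotopologues(
                vec, *[int(s[1:]) for s in frag.split("-")]
            )
            assert np.allclose(dist.fractions, ref, atol=1e-12)
        # total label agrees between whole molecule and fragment views
        mean_whole = sum(k * f for k, f in enumerate(whole.fractions))
        mean_frags = sum(
            sum(k * f for k, f in enumerate(
                to_isotopologues(vec, "glycogen", frag).fractions))
            for frag in ("C1-C4", "C3-C6")
        ) - sum(
            k * f for k, f in enumerate(
                to_isotopologues(vec, "glycogen", "C3-C4").fractions)
        )
        assert mean_frags == pytest.approx(mean_whole, rel=1e-9)
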