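"""Cellular-automata immune model: kinetics, walks, transitions, traces."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from ventilam.cell_ca import (ALIVE, DEAD, FIBROSIS, CAParams, CytokineField,
                              EpithelialCell, Lattice, StrainInput,
                              WanderingAgent, _move_agents, activation_gate,
                              ca_step, chemotaxis_step, diffuse_decay,
                              epithelial_update, init_state, release_probability,
                              run_ensemble, run_inflammation)

from .oracles import heat_kernel_decay


def field(conc, d=0.1, k=0.01):
    return CytokineField("TNF", np.asarray(conc, dtype=float), d, k)


class TestDiffuseDecay:
    def test_null_field_stays_null(self):
        out = diffuse_decay(field(np.zeros((8, 8))))
        assert not out.conc.any()

    def test_uniform_field_no_decay_unchanged(self):
        out = diffuse_decay(field(np.full((8, 8), 2.5), k=0.0))
        np.testing.assert_allclose(out.conc, 2.5, rtol=1e-14)

    def test_uniform_decay_matches_geometric_law(self):
        f = field(np.full((8, 8), 1.0), k=0.05)
        for n in range(10):
            f = diffuse_decay(f)
        np.testing.assert_allclose(f.conc, (1 - 0.05) ** 10, rtol=1e-12)

    def test_geometric_convergence_to_exponential(self):
        """As dt -> 0 the discrete decay approaches exp(-K t)."""
        errs = []
        for dt in (0.5, 0.25, 0.125):
            f = field(np.full((4, 4), 1.0), d=0.0, k=0.1)
            for _ in range(int(round(10 / dt))):
                f = diffuse_decay(f, dt=dt)
            errs.append(abs(f.conc[0, 0] - np.exp(-1.0)))
        assert errs[0] > errs[1] > errs[2]

    def test_stability_guard(self):
        with pytest.raises(ValueError, match="0.25"):
            diffuse_decay(field(np.zeros((5, 5)), d=0.3))

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10 ** 6), k=st.floats(0.0, 0.2))
    def test_mass_decays_geometrically_with_zero_flux(self, seed, k):
        """Zero-flux boundaries conserve mass up to the decay factor."""
        rng = np.random.default_rng(seed)
        f = field(rng.random((12, 9)), k=k)
        total0 = f.total()
        out = diffuse_decay(f)
        assert out.total() == pytest.approx((1 - k) * total0, rel=1e-12)

    def test_gaussian_pulse_matches_heat_kernel(self):
        n, sigma0, d, k, steps = 101, 5.0, 0.1, 0.001, 400
        x = np.arange(n) - n // 2
        xx, yy = np.meshgrid(x, x, indexing="ij")
        f = field(heat_kernel_decay(xx, yy, 0.0, sigma0, d, k), d=d, k=k)
        for _ in range(steps):
            f = diffuse_decay(f)
        exact = heat_kernel_decay(xx, yy, float(steps), sigma0, d, k)
        err = np.linalg.norm(f.conc - exact) / np.linalg.norm(exact)
        assert err < 0.01


class TestActivationGate:
    def test_zero_strain_zero_gate(self):
        assert activation_gate(0.0, CAParams()) == 0.0

    def test_saturates_well_above_threshold(self):
        p = CAParams()
        assert activation_gate(10 * p.eps_sat, p) == 1.0

    def test_monotone(self):
        p = CAParams()
        s = np.linspace(0, 2 * p.eps_sat, 500)
        g = activation_gate(s, p)
        assert np.all(np.diff(g) >= 0)
        assert np.all((g >= 0) & (g <= 1))


class TestReleaseProbability:
    def test_macrophage_suppressed_by_tgf(self):
        p = CAParams()
        assert release_probability("macrophage", None, 1e9, p) < 1e-9
        lo = release_probability("macrophage", None, 2.0, p)
        hi = release_probability("macrophage", None, 0.0, p)
        assert lo < hi == p.p_tnf_max

    def test_fibroblast_needs_tnf(self):
        assert release_probability("fibroblast", 0.0, None, CAParams()) == 0.0

    def test_half_saturation_identities(self):
        p = CAParams()
        assert release_probability("macrophage", None, p.c_half_suppress, p) == \
            pytest.approx(p.p_tnf_max / 2)
        assert release_probability("fibroblast", p.c_half_induce, None, p) == \
            pytest.approx(p.p_tgf_max / 2)

    def test_strain_gate_applies_to_macrophage(self):
        p = CAParams()
        assert release_probability("macrophage", None, 0.0, p, strain=0.0) == 0.0

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            release_probability("neutrophil", 0.0, 0.0, CAParams())


class TestChemotaxis:
    def test_uniform_field_unbiased(self):
        """Empirical move frequencies on a flat field are uniform (chi-square)."""
        rng = np.random.default_rng(0)
        conc = np.full((21, 21), 3.0)
        pos = np.tile([[10, 10]], (100_000, 1))
        new = _move_agents(pos, conc, beta=1.0, rng=rng)
        moves = (new - pos) @ np.array([5, 1])  # unique code per offset
        _, counts = np.unique(moves, return_counts=True)
        assert counts.size == 5
        assert chisquare(counts).pvalue > 0.01

    def test_beta_zero_ignores_gradient(self):
        rng = np.random.default_rng(1)
        conc = np.linspace(0, 10, 21)[None, :] * np.ones((21, 1))
        pos = np.tile([[10, 10]], (100_000, 1))
        new = _move_agents(pos, conc, beta=0.0, rng=rng)
        _, counts = np.unique((new - pos) @ np.array([5, 1]), return_counts=True)
        assert chisquare(counts).pvalue > 0.01

    def test_gradient_bias_matches_softmax_weights(self):
        """Linear gradient: frequencies match exp(beta C) weights to 3 sigma."""
        rng = np.random.default_rng(2)
        n = 100_000
        conc = 0.5 * np.arange(21)[None, :] * np.ones((21, 1))
        pos = np.tile([[10, 10]], (n, 1))
        new = _move_agents(pos, conc, beta=1.0, rng=rng)
        codes = (new - pos) @ np.array([5, 1])
        # candidates: stay, up, down, left, right with C = 5, 5, 5, 4.5, 5.5
        w = np.exp(np.array([5.0, 5.0, 5.0, 4.5, 5.5]))
        expect = w / w.sum()
        order = [0, -5, 5, -1, 1]
        for code, pr in zip(order, expect):
            freq = (codes == code).mean()
            sigma = np.sqrt(pr * (1 - pr) / n)
            assert abs(freq - pr) < 3.5 * sigma

    def test_boundary_agent_stays_on_lattice(self):
        rng = np.random.default_rng(3)
        conc = np.zeros((5, 5))
        pos = np.tile([[0, 0]], (10_000, 1))
        new = _move_agents(pos, conc, beta=1.0, rng=rng)
        assert new.min() >= 0

    def test_single_agent_wrapper(self):
        rng = np.random.default_rng(4)
        agent = WanderingAgent("macrophage", (2, 2))
        moved = chemotaxis_step(agent, field(np.zeros((5, 5))), 1.0, rng)
        assert abs(moved.position[0] - 2) + abs(moved.position[1] - 2) <= 1


class TestEpithelialUpdate:
    def test_alive_without_tnf_stays_alive(self):
        rng = np.random.default_rng(0)
        cell = EpithelialCell((0, 0), ALIVE)
        for _ in range(100):
            assert epithelial_update(cell, 0.0, 5.0, CAParams(), rng).state == ALIVE

    def test_dead_without_tgf_never_heals(self):
        rng = np.random.default_rng(0)
        cell = EpithelialCell((0, 0), DEAD)
        for _ in range(100):
            out = epithelial_update(cell, 5.0, 0.0, CAParams(), rng)
            assert out.state == DEAD
            cell = out

    def test_damage_rate_binomial_oracle(self):
        """At TNF = C_half the per-step death probability is p_damage_max/2."""
        p = CAParams()
        rng = np.random.default_rng(5)
        n = 40_000
        cell = EpithelialCell((0, 0), ALIVE)
        died = sum(epithelial_update(cell, p.c_half_damage, 0.0, p, rng).state == DEAD
                   for _ in range(n))
        pr = p.p_damage_max / 2
        assert abs(died / n - pr) < 3.5 * np.sqrt(pr * (1 - pr) / n)

    def test_fibrosis_requires_duration_and_tgf(self):
        p = CAParams(p_heal_max=0.0, p_fib=1.0)
        rng = np.random.default_rng(6)
        young = EpithelialCell((0, 0), DEAD, dead_since=0)
        assert epithelial_update(young, 0.0, 1.0, p, rng).state == DEAD
        old = EpithelialCell((0, 0), DEAD, dead_since=p.tau_fib)
        assert epithelial_update(old, 0.0, 1.0, p, rng).state == FIBROSIS
        assert epithelial_update(old, 0.0, 0.0, p, rng).state == DEAD

    def test_fibrosis_absorbing(self):
        rng = np.random.default_rng(7)
        cell = EpithelialCell((0, 0), FIBROSIS)
        assert epithelial_update(cell, 10.0, 10.0, CAParams(), rng).state == FIBROSIS


class TestCaStep:
    def test_quiescence_without_strain_or_cytokines(self):
        """Zero strain, zero cytokines: pure random walk, no transitions."""
        p = CAParams()
        rng = np.random.default_rng(0)
        state = init_state(p, Lattice(20, 20), rng)
        epi0 = state.epi.copy()
        for _ in range(50):
            ca_step(state, StrainInput(level=0.0), p, rng)
        np.testing.assert_array_equal(state.epi, epi0)
        assert state.tnf.total() == 0.0
        assert state.tgf.total() == 0.0

    def test_population_conserved(self):
        p = CAParams()
        rng = np.random.default_rng(1)
        state = init_state(p, Lattice(20, 20), rng)
        state.tnf.conc[10, 10] = 50.0  # seed an injury signal
        for _ in range(100):
            ca_step(state, StrainInput(level=1e-6), p, rng)
            assert sum(state.counts()) == state.population

    def test_seed_determinism(self):
        p = CAParams()
        s = StrainInput(level=7e-7)
        a = run_inflammation(s, p, n_steps=200, seed=11, lattice=Lattice(30, 30))
        b = run_inflammation(s, p, n_steps=200, seed=11, lattice=Lattice(30, 30))
        np.testing.assert_array_equal(a.dead, b.dead)
        np.testing.assert_array_equal(a.tnf_total, b.tnf_total)
        c = run_inflammation(s, p, n_steps=200, seed=12, lattice=Lattice(30, 30))
        assert not np.array_equal(a.tnf_total, c.tnf_total)


class TestRunInflammation:
    def test_subthreshold_strain_no_response(self):
        p = CAParams()
        tr = run_inflammation(StrainInput(level=0.5 * p.eps_act), p, n_steps=500,
                              seed=3, lattice=Lattice(40, 40))
        assert not tr.dead.any()
        assert not tr.fibrosis.any()

    def test_trace_bookkeeping(self):
        p = CAParams()
        tr = run_inflammation(StrainInput(level=7e-7), p, n_steps=100, seed=4,
                              lattice=Lattice(20, 20))
        assert tr.dead.size == 101
        np.testing.assert_array_equal(tr.alive + tr.dead + tr.fibrosis, 400)

    def test_fluctuating_strain_mode(self):
        s = StrainInput(level=5e-7, mode="fluctuating", amplitude=0.5, period=50)
        assert s.at_step(0) == pytest.approx(5e-7)
        vals = np.array([s.at_step(t) for t in range(50)])
        assert vals.min() >= 0 and vals.max() > 5e-7


class TestEnsemble:
    def test_reproducible_and_replicates_differ(self):
        p = CAParams()
        s = StrainInput(level=7e-7)
        e1 = run_ensemble(s, p, n_steps=150, n_reps=3, seed=5, lattice=Lattice(30, 30))
        e2 = run_ensemble(s, p, n_steps=150, n_reps=3, seed=5, lattice=Lattice(30, 30))
        np.testing.assert_array_equal(e1.mean_dead, e2.mean_dead)
        assert not np.array_equal(e1.traces[0].dead, e1.traces[1].dead)

    def test_mean_trace_smoother_than_members(self):
        """Averaging reduces total variation relative to every single trace."""
        p = CAParams()
        s = StrainInput(level=7e-7)
        ens = run_ensemble(s, p, n_steps=400, n_reps=8, seed=6, lattice=Lattice(40, 40))
        tv = lambda x: np.abs(np.diff(x)).sum()
        assert tv(ens.mean_dead) < min(tv(t.dead) for t in ens.traces)

    def test_dose_response_monotone_in_strain(self):
        """Mean peak dead count rises with the uniform strain level."""
        p = CAParams()
        peaks = []
        for level in (2.5e-7, 4.0e-7, 6.5e-7):
            ens = run_ensemble(StrainInput(level=level), p, n_steps=600,
                               n_reps=20, seed=7, lattice=Lattice(40, 40))
            peaks.append(ens.peak_heights.mean())
        assert peaks[0] < peaks[1] < peaks[2]


class TestValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            CAParams(p_damage_max=1.5)

    def test_bad_gate_rejected(self):
        with pytest.raises(ValueError):
            CAParams(eps_act=1e-6, eps_sat=1e-7)

    def test_small_lattice_rejected(self):
        with pytest.raises(ValueError):
            Lattice(2, 10)

    def test_negative_strain_rejected(self):
        with pytest.raises(ValueError):
            StrainInput(level=-1.0)
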