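"""Unit and property tests for the per-step cell dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perisylvian import ModelParams
from perisylvian.dynamics import (
    NetworkState,
    adaptive_threshold,
    excitatory_output,
    inhibitory_output,
    step_network,
    update_gliding_average,
    update_global_inhibition,
    update_membrane,
)

from conftest import make_toy_instance


class TestOutputFunctions:
    @pytest.mark.parametrize("offset,expected", [
        (-0.3, 0.0),    # below lower threshold
        (0.5, 0.5),     # unit slope between thresholds
        (7.0, 1.0),     # clipped at 1
        (0.0, 0.0),
        (1.0, 1.0),
    ])
    def test_excitatory_piecewise_linear(self, offset, expected):
        phi = 0.11
        assert excitatory_output(phi + offset, phi) == pytest.approx(expected)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-1, 1))
    @settings(derandomize=True, max_examples=50)
    def test_excitatory_monotone(self, v1, v2, phi):
        lo, hi = min(v1, v2), max(v1, v2)
        assert excitatory_output(lo, phi) <= excitatory_output(hi, phi)
        # nonincreasing in phi
        assert excitatory_output(hi, phi) >= excitatory_output(hi, phi + 0.5)

    @pytest.mark.parametrize("v,expected", [(-1.2, 0.0), (0.0, 0.0),
                                            (0.4, 0.4)])
    def test_inhibitory_rectifier(self, v, expected):
        assert inhibitory_output(v) == pytest.approx(expected)


class TestMembrane:
    def test_leak_factor(self, params):
        # one Euler step with no input: V' = (1 - dt/tau) V = 0.8 V
        assert update_membrane(1.0, 0.0, 0.0, params,
                               params.tau_e) == pytest.approx(0.8)
        assert update_membrane(0.0, 0.0, 0.0, params, params.tau_e) == 0.0

    def test_against_fine_step_ode(self, params):
        # subdividing the step must converge to the exact exponential decay
        for n, tol in ((1, 0.03), (100, 1e-3), (10000, 1e-5)):
            fine = params.replace(dt=params.dt / n)
            v = 1.0
            for _ in range(n):
                v = update_membrane(v, 0.0, 0.0, fine, params.tau_e)
            assert v == pytest.approx(np.exp(-params.dt / params.tau_e),
                                      abs=tol)

    def test_fixed_point_is_k1_vin(self, params):
        v, v_in = 0.0, 37.0
        for _ in range(300):
            v = update_membrane(v, v_in, 0.0, params, params.tau_e)
        assert v == pytest.approx(params.k1 * v_in, abs=1e-6)

    def test_nonpositive_tau_rejected(self, params):
        with pytest.raises(ValueError):
            update_membrane(0.0, 0.0, 0.0, params, 0.0)


class TestAverages:
    def test_gliding_average_fixed_point_and_limit(self):
        assert update_gliding_average(0.0, 0.0, 15.0, 0.5) == 0.0
        assert update_gliding_average(0.6, 0.6, 15.0, 0.5) == pytest.approx(0.6)
        om, prev = 0.0, -1.0
        for _ in range(300):
            prev, om = om, update_gliding_average(om, 1.0, 15.0, 0.5)
            assert om > prev  # monotone approach
        assert om == pytest.approx(1.0, abs=1e-3)

    def test_adaptive_threshold(self):
        assert adaptive_threshold(0.0, 0.026) == 0.0
        assert adaptive_threshold(1.0, 0.026) == pytest.approx(0.026)
        assert adaptive_threshold(0.2, 0.026) < adaptive_threshold(0.3, 0.026)
        assert adaptive_threshold(0.5, 0.026, base=0.1) == pytest.approx(0.113)

    def test_global_inhibition_tracks_area_output(self):
        assert update_global_inhibition(0.0, 0.0, 8.0, 0.5) == 0.0
        om = 0.0
        for _ in range(1000):
            om = update_global_inhibition(om, 0.7, 8.0, 0.5)
        assert om == pytest.approx(0.7, abs=1e-4)


def _naive_step(state, syn, ext, params, phase, noise):
    """Cell-by-cell pure-loop oracle of one synchronous update."""
    n_areas, side = syn.n_areas, syn.side
    ac = side * side
    n = syn.n_cells
    phi = [params.base_threshold + params.alpha * state.omega[x]
           for x in range(n)]
    O_e = [min(1.0, max(0.0, state.V_e[x] - phi[x])) for x in range(n)]
    O_i = [max(0.0, state.V_i[x]) for x in range(n)]
    exc = [0.0] * n
    for pre, post, w in zip(syn.pre, syn.post, syn.w):
        exc[post] += w * O_e[pre]
    pool = [0.0] * n
    for a in range(n_areas):
        for r in range(side):
            for c in range(side):
                s = 0.0
                for rr in range(max(0, r - 2), min(side, r + 3)):
                    for cc in range(max(0, c - 2), min(side, c + 3)):
                        s += O_e[a * ac + rr * side + cc]
                pool[a * ac + r * side + c] = s
    mean = [sum(O_e[a * ac:(a + 1) * ac]) / ac for a in range(n_areas)]
    ks, k2 = params.ks(phase), params.k2(phase)
    gamma = params.synaptic_gain
    new = NetworkState.zeros(n_areas, ac)
    for x in range(n):
        a = x // ac
        vin = gamma * (exc[x] - params.w_ie * O_i[x]
                       - ks * state.omega_S[a]) + (ext[x] if ext is not None else 0.0)
        gain = params.k1 * k2 if params.scale_noise_with_input else k2
        dv = -state.V_e[x] + params.k1 * vin + gain * noise[x]
        new.V_e[x] = state.V_e[x] + params.dt / params.tau_e * dv
        dvi = -state.V_i[x] + params.k1 * gamma * params.w_ei * pool[x]
        new.V_i[x] = state.V_i[x] + params.dt / params.tau_i * dvi
        new.omega[x] = state.omega[x] + params.dt / params.tau_A \
            * (O_e[x] - state.omega[x])
    for a in range(n_areas):
        new.omega_S[a] = state.omega_S[a] + params.dt / params.tau_S \
            * (mean[a] - state.omega_S[a])
    return new


class TestStepNetwork:
    def test_decay_to_zero_without_input(self, params, toy_instance):
        # isolated leak: no links, no inhibitory feedback, no noise
        p = params.replace(ks_train=0.0, w_ie=0.0, w_ei=0.0)
        syn = toy_instance.synapses
        syn.w[:] = 0.0
        state = NetworkState.zeros(syn.n_areas, syn.area_cells)
        rng = np.random.default_rng(0)
        state.V_e[:] = rng.normal(0, 1, syn.n_cells)
        norms = []
        for _ in range(60):
            state = step_network(state, syn, None, p, "train")
            norms.append(np.linalg.norm(state.V_e))
        assert norms[-1] < 1e-4
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_outputs_stay_clipped(self, params, toy_instance):
        syn = toy_instance.synapses
        state = NetworkState.zeros(syn.n_areas, syn.area_cells)
        rng = np.random.default_rng(1)
        ext = np.zeros(syn.n_cells)
        ext[:10] = 1000.0
        for t in range(40):
            noise = rng.random(syn.n_cells) - 0.5
            state = step_network(state, syn, ext if t < 5 else None, params,
                                 "train", noise=noise)
            phi = params.alpha * state.omega
            O = np.clip(state.V_e - phi, 0, 1)
            assert np.all(O >= 0) and np.all(O <= 1)
            assert np.all(np.maximum(state.V_i, 0) >= 0)

    def test_global_inhibition_is_negative_feedback(self, params,
                                                    toy_instance):
        # larger ks never increases the time-summed output on a fixed run
        syn = toy_instance.synapses
        rng = np.random.default_rng(2)
        noises = [rng.random(syn.n_cells) - 0.5 for _ in range(100)]
        ext = np.zeros(syn.n_cells)
        ext[:5] = 400.0
        sums = {}
        for ks in (10.0, 60.0, 120.0):
            p = params.replace(ks_test=ks)
            state = NetworkState.zeros(syn.n_areas, syn.area_cells)
            total = 0.0
            for t in range(100):
                state = step_network(state, syn, ext if t < 16 else None,
                                     p, "test", noise=noises[t])
                total += np.clip(state.V_e - p.alpha * state.omega, 0, 1).sum()
            sums[ks] = total
        assert sums[10.0] >= sums[60.0] >= sums[120.0]

    def test_matches_naive_loop_oracle(self, params, toy_instance):
        syn = toy_instance.synapses
        rng = np.random.default_rng(3)
        state = NetworkState.zeros(syn.n_areas, syn.area_cells)
        state.V_e[:] = rng.normal(0, 0.3, syn.n_cells)
        state.V_i[:] = rng.normal(0, 0.1, syn.n_cells)
        state.omega[:] = rng.random(syn.n_cells) * 0.2
        oracle = state.copy()
        ext = np.zeros(syn.n_cells)
        ext[::7] = 300.0
        for t in range(50):
            noise = rng.random(syn.n_cells) - 0.5
            state = step_network(state, syn, ext if t < 8 else None, params,
                                 "train", noise=noise)
            oracle = _naive_step(oracle, syn, ext if t < 8 else None, params,
                                 "train", noise)
            for field in ("V_e", "V_i", "omega", "omega_S"):
                np.testing.assert_allclose(getattr(state, field),
                                           getattr(oracle, field),
                                           rtol=0, atol=1e-10)

    def test_shape_mismatch_raises(self, params, toy_instance):
        syn = toy_instance.synapses
        bad = NetworkState.zeros(syn.n_areas + 1, syn.area_cells)
        with pytest.raises(ValueError):
            step_network(bad, syn, None, params, "train")


class TestKernelEquivalence:
    def test_kernel_matches_reference_with_plasticity(self, params):
        from perisylvian.plasticity import PlasticityRule, apply_plasticity
        from perisylvian.protocol import Runner

        inst = make_toy_instance(seed=5, side=5, n_areas=2, p0=0.8)
        rule = PlasticityRule.from_params(params)
        ref_syn = inst.synapses.copy()
        ref_state = NetworkState.zeros(2, 25)
        rng = np.random.default_rng(6)
        init_V = rng.normal(0, 0.4, 50)
        ref_state.V_e[:] = init_V
        runner = Runner(inst, params)
        runner.state.V_e[:] = init_V
        ext = np.zeros(50)
        ext[list(inst.patterns[0].a1_cells)] = 400.0

        rates, rec = runner.run(30, "train", plastic=True, ext=ext,
                                record=True, noise=False)
        for _ in range(30):
            O_e = np.clip(ref_state.V_e - params.alpha * ref_state.omega, 0, 1)
            V_t = ref_state.V_e.copy()
            ref_state = step_network(ref_state, ref_syn, ext, params, "train")
            apply_plasticity(ref_syn, O_e, V_t, rule)
        np.testing.assert_allclose(runner.state.V_e, ref_state.V_e, atol=1e-10)
        np.testing.assert_allclose(runner.state.V_i, ref_state.V_i, atol=1e-10)
        np.testing.assert_allclose(runner.state.omega, ref_state.omega,
                                   atol=1e-10)
        np.testing.assert_allclose(runner.state.omega_S, ref_state.omega_S,
                                   atol=1e-10)
        np.testing.assert_allclose(inst.synapses.w, ref_syn.w, atol=1e-12)
        # recorded frames are end-of-step outputs
        final_O = np.clip(runner.state.V_e
                          - params.alpha * runner.state.omega, 0, 1)
        np.testing.assert_allclose(rec[-1], final_O, atol=1e-12)
        np.testing.assert_allclose(rates[-1],
                                   [final_O[:25].sum(), final_O[25:].sum()],
                                   atol=1e-10)

    def test_deterministic_under_seed(self, params):
        from perisylvian.protocol import Runner
        inst = make_toy_instance(seed=7)
        outs = []
        for _ in range(2):
            r = Runner(inst, params)
            r.seed_noise(123)
            rates, _ = r.run(200, "train", plastic=False)
            outs.append(rates)
        np.testing.assert_array_equal(outs[0], outs[1])
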