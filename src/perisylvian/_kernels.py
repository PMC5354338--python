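"""Numba fast path for the simulation loop.

`run_block` advances the whole network by a block of time steps.  It is
algorithmically identical to one :func:`perisylvian.dynamics.step_network`
call followed by :func:`perisylvian.plasticity.apply_plasticity` per step
(time-t outputs and potentials, pre-update weights for propagation), but
exploits the sparsity of activity: synaptic propagation and inhibitory
pooling are scattered from the cells with nonzero output only, and the
plasticity pass touches only postsynaptic cells whose potential lies in an
LTP/LTD zone.  Per-step summed excitatory rates per area are always
returned; full per-cell output traces can be captured for testing trials.
Recorded rates are end-of-step outputs, i.e. the response after the step's
input has acted on the membrane.

Membrane noise comes from an inline xorshift64* generator whose 64-bit
state is owned by the caller, one uniform(-0.5, 0.5) draw per excitatory
cell per step.
"""

import numpy as np
from numba import njit

_U64 = np.uint64
_MASK = 0xFFFFFFFFFFFFFFFF
_INV_2_53 = 1.0 / 9007199254740992.0


def seed_state(seed: int) -> np.ndarray:
    """SplitMix64-expanded, never-zero xorshift64* state for ``seed``."""
    z = (int(seed) + 0x9E3779B97F4A7C15) & _MASK
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
    z = z ^ (z >> 31)
    return np.array([z or 0x9E3779B97F4A7C15], dtype=np.uint64)


@njit(cache=True)
def run_block(V_e, V_i, omega, omega_S,
              pindptr, post_of, w, indptr, pre_of, wpos,
              n_areas, side, ihalf,
              n_steps, ext,
              dt, tau_e, tau_i, k1, noise_gain, ks, gamma,
              alpha, base_th, tau_A, tau_S, w_ei, w_ie,
              plastic, th_pre, th_plus, th_minus, dw, w_max,
              homo_below, hetero_on, ltp_on, noise_on,
              rng_state, area_rates, record):
    n_cells = V_e.shape[0]
    area_cells = side * side
    inv_e = dt / tau_e
    inv_i = dt / tau_i
    gA = dt / tau_A
    gS = dt / tau_S
    O_e = np.empty(n_cells)
    exc_in = np.empty(n_cells)
    pool = np.empty(n_cells)
    mean_t = np.empty(n_areas)
    do_record = record.shape[0] == n_steps
    rs = rng_state[0]
    c12 = _U64(12)
    c25 = _U64(25)
    c27 = _U64(27)
    c11 = _U64(11)
    cmul = _U64(2685821657736338717)

    for t in range(n_steps):
        # (1) outputs from current potentials, and area means
        for a in range(n_areas):
            s = 0.0
            for x in range(a * area_cells, (a + 1) * area_cells):
                o = V_e[x] - (base_th + alpha * omega[x])
                o = 0.0 if o < 0.0 else (1.0 if o > 1.0 else o)
                O_e[x] = o
                s += o
            mean_t[a] = s / area_cells

        # (2) excitatory propagation and local pooling, scattered from the
        #     active cells; silent cells contribute nothing by construction
        for x in range(n_cells):
            exc_in[x] = 0.0
            pool[x] = 0.0
        for src in range(n_cells):
            o = O_e[src]
            if o > 0.0:
                for k in range(pindptr[src], pindptr[src + 1]):
                    exc_in[post_of[k]] += w[k] * o
                a = src // area_cells
                rem = src - a * area_cells
                r = rem // side
                c = rem - r * side
                r0 = r - ihalf if r - ihalf > 0 else 0
                r1 = r + ihalf if r + ihalf < side - 1 else side - 1
                c0 = c - ihalf if c - ihalf > 0 else 0
                c1 = c + ihalf if c + ihalf < side - 1 else side - 1
                base = a * area_cells
                for rr in range(r0, r1 + 1):
                    row = base + rr * side
                    for cc in range(c0, c1 + 1):
                        pool[row + cc] += o

        # (3) plasticity from time-t outputs and potentials (weights were
        #     already read for propagation, so updates act "after" the step)
        if plastic:
            for post in range(n_cells):
                vp = V_e[post]
                depol = vp >= th_plus
                if homo_below:
                    ltd = vp < th_minus
                else:
                    ltd = (vp >= th_minus) and (vp < th_plus)
                if depol:
                    for j in range(indptr[post], indptr[post + 1]):
                        k = wpos[j]
                        if O_e[pre_of[j]] > th_pre:
                            if ltp_on:
                                nw = w[k] + dw
                                w[k] = w_max if nw > w_max else nw
                        elif hetero_on:
                            nw = w[k] - dw
                            w[k] = 0.0 if nw < 0.0 else nw
                elif ltd:
                    for j in range(indptr[post], indptr[post + 1]):
                        if O_e[pre_of[j]] > th_pre:
                            k = wpos[j]
                            nw = w[k] - dw
                            w[k] = 0.0 if nw < 0.0 else nw

        # (4) membranes (global inhibition from the pre-update omega_S),
        #     gliding averages, and end-of-step responses, fused per area
        for a in range(n_areas):
            ginh = ks * omega_S[a]
            base = a * area_cells
            s_end = 0.0
            for x in range(base, base + area_cells):
                vi = V_i[x]
                oi = vi if vi > 0.0 else 0.0
                vin = gamma * (exc_in[x] - w_ie * oi - ginh) + ext[x]
                nz = 0.0
                if noise_on:
                    rs ^= rs >> c12
                    rs ^= rs << c25
                    rs ^= rs >> c27
                    nz = float((rs * cmul) >> c11) * _INV_2_53 - 0.5
                V_e[x] += inv_e * (-V_e[x] + k1 * vin + noise_gain * nz)
                V_i[x] = vi + inv_i * (-vi + k1 * gamma * w_ei * pool[x])
                om = omega[x] + gA * (O_e[x] - omega[x])
                omega[x] = om
                o = V_e[x] - (base_th + alpha * om)
                o = 0.0 if o < 0.0 else (1.0 if o > 1.0 else o)
                if do_record:
                    record[t, x] = o
                s_end += o
            area_rates[t, a] = s_end
            omega_S[a] += gS * (mean_t[a] - omega_S[a])

    rng_state[0] = rs
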