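"""Graded-response cell dynamics: the per-time-step update rules.

Every cell is a leaky integrator over its net input, integrated with the
Euler scheme (step ``dt``).  Excitatory cells emit a piecewise-linear output
clipped to [0, 1] above an adaptive threshold that tracks their recent mean
activity; inhibitory cells emit ``max(V, 0)``.  Each area carries a single
gliding average of its mean excitatory output which feeds back as
area-specific ("global") inhibition.

This module is the readable numpy reference; the numba fast path in
``_kernels`` implements the identical algorithm and is cross-checked against
it in the test suite.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.ndimage

from .connectivity import NEIGHBORHOOD_I, SynapseSet
from .params import TRAIN, ModelParams

__all__ = [
    "excitatory_output", "inhibitory_output", "update_membrane",
    "update_gliding_average", "adaptive_threshold", "update_global_inhibition",
    "NetworkState", "step_network",
]


def excitatory_output(V, phi):
    """Piecewise-linear output: 0 below ``phi``, slope 1 up to ``phi + 1``,
    clipped at 1.  Monotone nondecreasing in V, nonincreasing in phi."""
    return np.clip(np.asarray(V) - phi, 0.0, 1.0)


def inhibitory_output(V):
    """Inhibitory cells output their potential, rectified at zero."""
    return np.maximum(np.asarray(V), 0.0)


def update_membrane(V, V_in, noise_draw, params: ModelParams, tau: float,
                    k2: float = 0.0):
    """One Euler step of the leaky integrator tau*dV/dt = -V + k1*V_in + noise.

    The noise term is ``k1*k2*noise_draw`` when
    ``params.scale_noise_with_input`` (default) and ``k2*noise_draw``
    otherwise; ``noise_draw`` is uniform on (-0.5, 0.5).  With constant input
    the iteration converges to ``k1 * V_in``.
    """
    if tau <= 0:
        raise ValueError("tau must be strictly positive")
    gain = params.k1 * k2 if params.scale_noise_with_input else k2
    dVdt = -np.asarray(V) + params.k1 * np.asarray(V_in) + gain * np.asarray(noise_draw)
    return V + (params.dt / tau) * dVdt


def update_gliding_average(omega, O, tau_A: float, dt: float):
    """One Euler step of the low-pass filter tau_A * domega/dt = -omega + O."""
    if tau_A <= 0:
        raise ValueError("tau_A must be strictly positive")
    return omega + (dt / tau_A) * (np.asarray(O) - omega)

def adaptive_threshold(omega, alpha: float, base: float = 0.0):
    """Output threshold tracking recent activity: phi = base + alpha*omega."""
    return base + alpha * np.asarray(omega)


def update_global_inhibition(omega_S, area_output, tau_S: float, dt: float):
    """Low-pass of the area's mean excitatory output (one value per area);
    the ``ks * omega_S`` term is subtracted from every excitatory cell's
    net input on the next step."""
    if tau_S <= 0:
        raise ValueError("tau_S must be strictly positive")
    return omega_S + (dt / tau_S) * (np.asarray(area_output) - omega_S)


@dataclasses.dataclass
class NetworkState:
    """Time-varying state of all cells, flat area-major layout."""

    V_e: np.ndarray      # excitatory membrane potentials, (n_cells,)
    V_i: np.ndarray      # inhibitory membrane potentials, (n_cells,)
    omega: np.ndarray    # per-excitatory-cell gliding output average
    omega_S: np.ndarray  # per-area gliding average of mean output, (n_areas,)

    @classmethod
    def zeros(cls, n_areas: int, area_cells: int) -> "NetworkState":
        n = n_areas * area_cells
        return cls(np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n_areas))

    def copy(self) -> "NetworkState":
        return NetworkState(self.V_e.copy(), self.V_i.copy(),
                            self.omega.copy(), self.omega_S.copy())


def _pool_box(O_e: np.ndarray, n_areas: int, side: int,
              window: int = NEIGHBORHOOD_I) -> np.ndarray:
    """Clipped window x window box sum of the excitatory output per area."""
    grids = O_e.reshape(n_areas, side, side)
    kernel = np.ones((1, window, window))
    return scipy.ndimage.convolve(grids, kernel, mode="constant", cval=0.0
                                  ).reshape(n_areas * side * side)


def step_network(
    state: NetworkState,
    synapses: SynapseSet,
    external_input: np.ndarray | None,
    params: ModelParams,
    phase: str = TRAIN,
    noise: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Advance all areas by one simulation time step (synchronous update).

    Order of operations: (1) all outputs from the current potentials,
    (2) propagate outputs through excitatory links and the fixed inhibitory
    wiring to form each cell's net input, (3) update the gliding averages and
    the adaptive thresholds, (4) Euler-update all membrane potentials with
    fresh noise draws.  Only time-t outputs appear on the right-hand side.
    Plasticity is applied separately (see :mod:`perisylvian.plasticity`).

    ``noise`` is a pre-drawn uniform(-0.5, 0.5) array for the excitatory
    cells; if absent and ``rng`` is given, draws are taken from ``rng``;
    otherwise the step is noise-free.
    """
    n_areas, side = synapses.n_areas, synapses.side
    area_cells = side * side
    if state.V_e.shape[0] != synapses.n_cells:
        raise ValueError("state size does not match synapse set")
    if external_input is not None and external_input.shape != state.V_e.shape:
        raise ValueError("external input shape mismatch")

    phi = adaptive_threshold(state.omega, params.alpha, params.base_threshold)
    O_e = excitatory_output(state.V_e, phi)
    O_i = inhibitory_output(state.V_i)

    exc_in = synapses.csr_matrix() @ O_e
    pool = _pool_box(O_e, n_areas, side)
    area_mean = O_e.reshape(n_areas, area_cells).mean(axis=1)

    new_omega = update_gliding_average(state.omega, O_e, params.tau_A, params.dt)
    new_omega_S = update_global_inhibition(state.omega_S, area_mean,
                                           params.tau_S, params.dt)

    ks = params.ks(phase)
    gamma = params.synaptic_gain
    global_inh = np.repeat(ks * state.omega_S, area_cells)
    V_in_e = gamma * (exc_in - params.w_ie * O_i - global_inh)
    if external_input is not None:
        V_in_e = V_in_e + external_input

    if noise is None and rng is not None:
        noise = rng.random(state.V_e.shape) - 0.5
    if noise is None:
        noise = 0.0

    V_e = update_membrane(state.V_e, V_in_e, noise, params, params.tau_e,
                          k2=params.k2(phase))
    V_i = update_membrane(state.V_i, gamma * params.w_ei * pool, 0.0, params,
                          params.tau_i)
    return NetworkState(V_e, V_i, new_omega, new_omega_S)
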