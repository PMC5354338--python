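"""Training and testing protocols.

Training presents the 14 sensorimotor patterns in random order, 16 steps of
joint A1+M1 stimulation each, followed by a noise-only interstimulus interval
(ISI) of at least 30 steps that lasts until network activity has returned to
the pre-established noise baseline.  Hebbian plasticity is active throughout,
stimulation and ISIs alike, under the learning-phase noise and inhibition
constants.  Testing presents the auditory (A1) half of each learned pattern
for 2 steps under the testing-phase constants with plasticity frozen, and
records 10 pre-stimulation steps plus the 32 steps from stimulus onset.

The two members of an architecture pair are driven through *identical*
curricula: pattern set, presentation order and per-trial noise seeds are all
derived from the shared instance seed, so the only difference within a pair
is the long-distance connectivity.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import _kernels
from .connectivity import NEIGHBORHOOD_I, NetworkInstance
from .dynamics import NetworkState
from .params import TEST, TRAIN, ModelParams
from .stimuli import pattern_to_input

logger = logging.getLogger(__name__)

#: checkpoint schedule of the full-scale study (presentations per pattern)
FULL_CHECKPOINTS = (50, 100, 200, 500, 1000, 1500, 2000, 6000, 10000)


@dataclasses.dataclass(frozen=True)
class TrainingSchedule:
    """Presentation counts are per pattern; a checkpoint at c stores the
    weights after c presentations of every pattern."""

    checkpoints: tuple[int, ...] = FULL_CHECKPOINTS
    stim_steps: int = 16
    isi_min: int = 30
    isi_cap: int = 100
    baseline_window: int = 5
    calibration_steps: int = 200

    def __post_init__(self):
        if tuple(sorted(self.checkpoints)) != tuple(self.checkpoints):
            raise ValueError("checkpoints must be increasing")
        if self.isi_cap < self.isi_min:
            raise ValueError("isi_cap must be >= isi_min")

    @property
    def presentations_per_pattern(self) -> int:
        return self.checkpoints[-1]


@dataclasses.dataclass(frozen=True)
class BaselineReference:
    """Noise-only per-step summed-rate statistics, one value per area."""

    mean: np.ndarray
    sd: np.ndarray


def baseline_reached(area_sums_window: np.ndarray,
                     noise_reference: BaselineReference) -> bool:
    """True when every area's summed output in every step of the window is at
    or below its noise-only mean + 2 SD (boundary inclusive).  Being *below*
    baseline counts as returned: the criterion asks that activity no longer
    be elevated."""
    thr = noise_reference.mean + 2.0 * noise_reference.sd
    return bool(np.all(area_sums_window <= thr[None, :]))


def _trial_seed(seed: int, stream: int, trial: int) -> int:
    """Deterministic 32-bit noise seed for one trial of one stream."""
    return int(np.random.SeedSequence([seed, stream, trial]).generate_state(1)[0])


class Runner:
    """Bundles a network instance, parameters and dynamic state, and drives
    the numba kernel in blocks of steps."""

    def __init__(self, instance: NetworkInstance, params: ModelParams,
                 state: NetworkState | None = None):
        self.instance = instance
        self.params = params
        syn = instance.synapses
        self.state = state or NetworkState.zeros(syn.n_areas, syn.area_cells)
        self._zero_ext = np.zeros(syn.n_cells)
        self._rng_state = _kernels.seed_state(0)

    def seed_noise(self, seed: int) -> None:
        self._rng_state = _kernels.seed_state(seed)

    def run(self, n_steps: int, phase: str, plastic: bool,
            ext: np.ndarray | None = None, record: bool = False,
            noise: bool = True):
        """Advance ``n_steps``; returns (per-step area sums, optional full
        end-of-step excitatory output traces)."""
        syn = self.instance.synapses
        p = self.params
        st = self.state
        area_rates = np.empty((n_steps, syn.n_areas))
        rec = np.empty((n_steps, syn.n_cells)) if record else np.empty((0, 0))
        indptr, pre_of, wpos = syn.afferent_arrays()
        _kernels.run_block(
            st.V_e, st.V_i, st.omega, st.omega_S,
            syn.pindptr, syn.post, syn.w, indptr, pre_of, wpos,
            syn.n_areas, syn.side, NEIGHBORHOOD_I // 2,
            n_steps, self._zero_ext if ext is None else ext,
            p.dt, p.tau_e, p.tau_i, p.k1, p.noise_gain(phase), p.ks(phase),
            p.synaptic_gain, p.alpha, p.base_threshold, p.tau_A, p.tau_S,
            p.w_ei, p.w_ie,
            plastic, p.theta_pre, p.theta_plus, p.theta_minus, p.delta_w,
            p.w_max, p.homosynaptic_ltd == "below", p.heterosynaptic_ltd,
            p.ltp, noise,
            self._rng_state, area_rates, rec)
        return area_rates, rec

    def run_to_baseline(self, min_steps: int, cap: int, phase: str,
                        plastic: bool, ref: BaselineReference,
                        window: int = 5):
        """Noise-only interval: at least ``min_steps`` steps, extended one
        step at a time until the last ``window`` steps are back at baseline
        or ``cap`` steps have elapsed.  Returns (n_steps, capped)."""
        rates, _ = self.run(min_steps, phase, plastic)
        tail = rates[-window:]
        steps = min_steps
        while not baseline_reached(tail, ref) and steps < cap:
            one, _ = self.run(1, phase, plastic)
            tail = np.vstack([tail[1:], one])
            steps += 1
        return steps, steps >= cap and not baseline_reached(tail, ref)


def calibrate_baseline(instance: NetworkInstance, params: ModelParams,
                       phase: str, seed: int, n_steps: int = 200,
                       warmup: int = 50) -> BaselineReference:
    """Estimate the noise-only summed-rate baseline of each area on a fresh
    state copy (the network itself is not advanced)."""
    runner = Runner(instance, params)
    runner.seed_noise(_trial_seed(seed, 0, 0))
    rates, _ = runner.run(n_steps + warmup, phase, plastic=False)
    body = rates[warmup:]
    return BaselineReference(body.mean(axis=0), body.std(axis=0, ddof=1))


def presentation_order(seed: int, n_patterns: int,
                       n_presentations: int) -> np.ndarray:
    """Block-randomised order: within every block of ``n_patterns`` trials
    each pattern appears exactly once, in a fresh random permutation."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    blocks = [rng.permutation(n_patterns) for _ in range(n_presentations)]
    if not blocks:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(blocks)


@dataclasses.dataclass
class TrainResult:
    checkpoints: dict[int, np.ndarray]          # per-pattern count -> weights
    checkpoint_states: dict[int, NetworkState]  # state snapshots for resume
    state: NetworkState
    baseline: BaselineReference
    isi_cap_hits: int
    order: np.ndarray
    trials_run: int


def train(instance: NetworkInstance, params: ModelParams,
          schedule: TrainingSchedule, seed: int,
          resume_from: tuple[int, NetworkState, np.ndarray] | None = None,
          ) -> TrainResult:
    """Run the learning phase; weights are updated in place on
    ``instance.synapses`` and snapshotted at every scheduled checkpoint.

    ``seed`` drives pattern order and per-trial noise; pass the same seed to
    both members of a pair (their curricula are then identical).
    ``resume_from`` = (presentations_done, state, weights) restarts training
    after a stored checkpoint with an identical continuation.
    """
    n_patterns = len(instance.patterns)
    order = presentation_order(seed, n_patterns,
                               schedule.presentations_per_pattern)
    baseline = calibrate_baseline(instance, params, TRAIN, seed,
                                  schedule.calibration_steps)

    start_trial = 0
    state = None
    if resume_from is not None:
        done, state, weights = resume_from
        instance.synapses.w[:] = weights
        start_trial = done * n_patterns
    runner = Runner(instance, params, state)

    ext_cache = {
        p.pattern_id: pattern_to_input(
            p, params.stim_amplitude, instance.synapses.n_areas,
            instance.synapses.area_cells)
        for p in instance.patterns
    }
    checkpoint_trials = {c * n_patterns: c for c in schedule.checkpoints}
    checkpoints: dict[int, np.ndarray] = {}
    checkpoint_states: dict[int, NetworkState] = {}
    if 0 in schedule.checkpoints:   # checkpoint of the untrained network
        checkpoints[0] = instance.synapses.w.copy()
        checkpoint_states[0] = runner.state.copy()
    cap_hits = 0
    total = schedule.presentations_per_pattern * n_patterns
    for trial in range(start_trial, total):
        runner.seed_noise(_trial_seed(seed, 2, trial))
        pat = instance.patterns[order[trial]]
        runner.run(schedule.stim_steps, TRAIN, plastic=True,
                   ext=ext_cache[pat.pattern_id])
        _, capped = runner.run_to_baseline(
            schedule.isi_min, schedule.isi_cap, TRAIN, plastic=True,
            ref=baseline, window=schedule.baseline_window)
        if capped:
            cap_hits += 1
            logger.warning("ISI cap reached at trial %d", trial)
        if trial + 1 in checkpoint_trials:
            c = checkpoint_trials[trial + 1]
            checkpoints[c] = instance.synapses.w.copy()
            checkpoint_states[c] = runner.state.copy()
    return TrainResult(checkpoints, checkpoint_states, runner.state,
                       baseline, cap_hits, order, total - start_trial)


@dataclasses.dataclass
class TrialRecording:
    """One auditory-only testing trial.

    ``area_sums``: (n_areas, 32) summed excitatory rates over the 2
    stimulation steps plus 30 post steps.  ``prestim_sums``: (n_areas, 10)
    the 10 steps immediately before stimulation.  ``cell_traces``:
    (n_cells, 32) full excitatory record.
    """

    area_sums: np.ndarray
    prestim_sums: np.ndarray
    cell_traces: np.ndarray
    pattern_id: int
    architecture: str
    instance_seed: int

    @property
    def post_area_sums(self) -> np.ndarray:
        """(n_areas, 30) poststimulation portion."""
        return self.area_sums[:, 2:]

    @property
    def post_cell_traces(self) -> np.ndarray:
        return self.cell_traces[:, 2:]


def test(instance: NetworkInstance, params: ModelParams, seed: int,
         weights: np.ndarray | None = None, stim_steps: int = 2,
         post_steps: int = 30, prestim_steps: int = 10,
         washout_min: int = 30, washout_cap: int = 100) -> list[TrialRecording]:
    """Auditory-only testing: each learned pattern probed once, in random
    order, with plasticity frozen and the testing-phase constants active.
    Each trial starts from a noise-only washout back to baseline so no
    activity carries over between probes."""
    syn = instance.synapses
    saved_w = syn.w.copy()
    if weights is not None:
        syn.w[:] = weights
    try:
        baseline = calibrate_baseline(instance, params, TEST, seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
        order = rng.permutation(len(instance.patterns))
        runner = Runner(instance, params)
        recordings = []
        for k, pat_idx in enumerate(order):
            pat = instance.patterns[pat_idx]
            runner.seed_noise(_trial_seed(seed, 4, k))
            runner.run_to_baseline(washout_min, washout_cap, TEST,
                                   plastic=False, ref=baseline)
            pre_rates, _ = runner.run(prestim_steps, TEST, plastic=False)
            ext = pattern_to_input(pat, params.stim_amplitude, syn.n_areas,
                                   syn.area_cells, auditory_only=True)
            stim_rates, stim_rec = runner.run(stim_steps, TEST, plastic=False,
                                              ext=ext, record=True)
            post_rates, post_rec = runner.run(post_steps, TEST, plastic=False,
                                              record=True)
            recordings.append(TrialRecording(
                area_sums=np.vstack([stim_rates, post_rates]).T,
                prestim_sums=pre_rates.T,
                cell_traces=np.vstack([stim_rec, post_rec]).T,
                pattern_id=pat.pattern_id,
                architecture=instance.tag,
                instance_seed=instance.instance_seed,
            ))
        assert np.array_equal(syn.w, weights if weights is not None else saved_w), \
            "weights changed during testing"
        return recordings
    finally:
        syn.w[:] = saved_w
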