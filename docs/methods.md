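# Methods

## The model in brief

The package simulates six reciprocally connected cortical areas of the
perisylvian language system — A1, AB, PB (auditory stream) and PF, PM, M1
(articulatory stream) — as grids of 25 × 25 graded-response excitatory cells,
each paired with an inhibitory cell representing the interneuron cluster of
its cortical column.  Two architectures are compared as exact twins: the
*monkey architecture* (MA) links only adjacent areas of the chain
A1–AB–PB–PF–PM–M1, while the *human architecture* (HA) adds reciprocal
"jumping" projections A1–PB, AB–PF, PB–PM and PF–M1, emulating the
human-specific strength of the arcuate fasciculus.  The HA member of a pair
is built first; the MA member is a copy with the jumping links deleted, so
initial weights, word patterns and curricula are shared and architecture is
a within-subject factor.

Learning material is the package's own synthetic data: 14 "words", each a
random set of 17 A1 cells plus 17 M1 cells (2.72 % of each primary area),
activated jointly during training (16 steps per presentation, noise-only
intervals of ≥ 30 steps in between, Hebbian plasticity always on).  Testing
presents the auditory half alone for 2 steps with plasticity frozen and
records 10 pre-stimulus steps plus 32 steps from stimulus onset.

## Cell dynamics

Each cell is a leaky integrator, advanced with the Euler scheme
(Δt = 0.5, one "simulation time step" = one Euler update):

    τ dV/dt = −V + k1 · V_in + k1·k2 · η,        η ~ U(−0.5, 0.5) i.i.d.

Excitatory output is piecewise linear with unit slope between an adaptive
threshold φ and φ + 1, clipped to [0, 1]; inhibitory output is max(V, 0).
The threshold tracks the cell's recent activity, φ = α·ω, where ω is a
low-pass of the output with time constant τ_A (neuronal adaptation).  Each
area also carries one gliding average ω_S of its mean excitatory output
(time constant τ_S); the term k_s·ω_S is subtracted from every excitatory
cell's net input of that area (area-specific "global" inhibition, a slow
negative feedback on total activity).  Local competition comes from the
column inhibitory cells, which pool excitatory output over a 5 × 5
neighbourhood and project back onto their own column.

Two reconstruction choices deserve emphasis, because the model family's
membrane equation is often reproduced ambiguously:

* **Noise scaling.**  The noise term is scaled together with the input,
  k1·(V_in + k2·η).  The printed noise constants k2 = 15·√48 (training) and
  5·√48 (testing) then give an input noise s.d. of exactly 0.30 and 0.10 —
  the same order as the plasticity thresholds (0.15), which is the only
  reading under which those thresholds are meaningful.  A flag
  (`scale_noise_with_input`) restores the unscaled variant.
* **Synaptic gain.**  Synaptic weights are initialised uniformly on
  [0, 0.1].  Applied through the bare k1 = 0.01, a cell's entire afferent
  drive would be ≲ 10⁻² potential units — activity could never propagate
  beyond the stimulated cells.  The package therefore applies an explicit
  gain γ (default 1/k1 = 100) to the summed synaptic and inhibitory input
  inside V_in, so that a unit weight contributes a unit potential while
  external stimulus and noise are scaled by k1 as printed.  γ is a plain
  unit conversion between "weight units" and potential units, exposed in
  the configuration.

The update is synchronous: outputs are computed from time-t potentials,
propagated, and all potentials advance together — results are independent
of cell ordering.  Per step, the order is (1) outputs, (2) synaptic
propagation and inhibitory pooling, (3) gliding averages and thresholds,
(4) membrane updates with fresh noise.

## Connectivity

Excitatory links exist within every area and along every projection of the
architecture graph.  A candidate link from cell (r₁,c₁) to cell (r₂,c₂)
(between-area projections map identical grid coordinates) is realised with
probability p₀·exp(−d²/2σ²), clipped to zero outside a 19 × 19 window;
within-area self-links are excluded; windows are clipped at the grid border
(no wrap-around).  σ and p₀ are not constrained by any published value; the
defaults σ = 4.5 and p₀ = 0.457 give a mean within-window acceptance of
≈ 0.15 — about 54 afferents per cell per projection, a sparse, patchy,
topographic wiring.  Between-area windows use the same Gaussian profile as
within-area ones (the model family treats them jointly).  Jumping
projections are statistically identical to next-neighbour ones, so the HA
carries ≈ 9/5 the between-area links of its MA twin.

Inhibitory wiring is deterministic and non-plastic: every column's
inhibitory cell pools its 5 × 5 neighbourhood with gain `w_ei` and feeds
back with gain `w_ie`.

## Plasticity

All excitatory links follow the Artola–Bröcher–Singer rule, discretised to
two fixed levels ±Δw and gated by presynaptic output and postsynaptic
potential:

| presynaptic output | postsynaptic potential | change |
|---|---|---|
| > θ_pre | ≥ θ₊ | +Δw (LTP) |
| > θ_pre | θ₋ ≤ V < θ₊ | −Δw (homosynaptic LTD) |
| ≤ θ_pre | ≥ θ₊ | −Δw (heterosynaptic LTD) |
| otherwise | | 0 |

Weights are clipped to [0, w_max].  At the published thresholds
θ₋ = θ₊ = 0.15 the homosynaptic LTD band is empty, so learning reduces to
LTP between co-active cells plus heterosynaptic depression of inactive
afferents onto strongly depolarised cells — which is what prunes
non-members out of a forming assembly.  An alternative reading (depression
for V < θ₋, `homosynaptic_ltd="below"`) is available for sensitivity
analyses; under it, every active presynapse onto a sub-threshold cell is
depressed ~14× more often than potentiated, and no distributed assemblies
can form — one reason the band semantics is the default.

## Parameters

Printed constants (single source of truth in `ModelParams`): τ_e = 2.5,
τ_i = 5 steps; k1 = 0.01; k2 = 15√48 (train) / 5√48 (test); k_s = 95
(train) / 60 (test); α = 0.026; τ_A = 15; τ_S = 8; θ₊ = θ₋ = 0.15;
θ_pre = 0.05; Δw = 0.0007; Δt = 0.5.

Free parameters, chosen once during model development for a regime in which
(i) training ISIs reliably return to baseline, (ii) assemblies form and
saturate within the checkpoint range, and (iii) trained HA networks sustain
post-stimulus reverberation while MA networks do not:

| name | default | units | role |
|---|---|---|---|
| `synaptic_gain` γ | 100 (=1/k1) | – | weight-to-potential conversion |
| `w_max` | 0.45 | weight units | plasticity ceiling |
| `w_ei` | 0.5 | weight units | excitatory→inhibitory pooling gain |
| `w_ie` | 3.5 | weight units | inhibitory→excitatory feedback gain |
| `stim_amplitude` | 500 | V_in units | k1·500 = 5 potential units per stimulated cell |
| `base_threshold` | 0 | potential | resting output threshold |
| σ, p₀ | 4.5, 0.457 | cells, – | Gaussian link profile |

The stimulation amplitude saturates driven cells within 2–3 steps, well
above the ignition floor; results are insensitive to its exact value.

## Measurements

* **Cell assembly (CA).**  After auditory-only probing, a cell belongs to a
  word's assembly iff at any of the 30 post-stimulation steps its rate
  reaches ≥ 50 % of the maximally responsive cell of its area *at that
  step*, provided that maximum is ≥ 0.2.  (A global-maximum variant exists
  behind a flag.)
* **T_max.**  The 1-based step of the peak summed rate per area within the
  30 post-stimulation steps; ties resolve to the earliest step.
* **SMP.**  Consecutive steps from T_max during which the summed rate stays
  ≥ prestimulation mean + 2 SD (10 prestimulus steps; a zero SD receives a
  10⁻⁹ epsilon).  The first sub-threshold step ends the interval; later
  suprathreshold episodes are ignored.
* **Growth rate.**  Centred finite differences of mean CA size over the
  checkpoint grid (`numpy.gradient`, one-sided at the ends), rescaled to
  cells per 100 learning trials.
* **Statistics.**  Per-instance means over the 14 words enter two-way
  repeated-measures ANOVAs (architecture × area, Greenhouse–Geisser
  corrected, via pingouin); error bars use the within-subject SEM
  (per-subject grand means removed before computing the SEM).  The
  within-subject unit is the network instance.

## Protocol details and numerical choices

* The ISI baseline criterion is one-sided: the interval ends once every
  area's summed rate over the last 5 steps is at or below its noise-only
  mean + 2 SD (estimated from a 200-step calibration run per network and
  phase).  Being *below* baseline counts as returned — after strong
  ignitions the global-inhibition rebound briefly undershoots, and a
  two-sided criterion would deadlock there.  A 100-step cap guards against
  non-returning activity and is logged whenever hit.
* Testing trials are separated by a noise-only washout to the same baseline
  criterion, so no activity carries over between probes.
* Membrane noise comes from an inline xorshift64* generator (one uniform
  draw per excitatory cell per step), seeded per trial from the instance
  seed, so pair members experience identical noise streams while their
  trial structure stays aligned.  All randomness in the package derives
  from explicit seeds; end-to-end runs are bit-reproducible.
* The production kernel (numba) is algorithmically identical to the numpy
  reference implementation (`dynamics.step_network` + plasticity) — the
  test suite asserts agreement to 10⁻¹⁰ — but scatters synaptic input from
  active cells only and touches plastic rows only where the postsynaptic
  potential lies in an LTP/LTD zone.
* Recorded rates are end-of-step outputs (the response after the step's
  input has acted), so the first recorded stimulation frame already shows
  stimulus-driven activity.

## Problem sizes

The full-scale study design is 12 instance pairs and checkpoints to 10,000
presentations per pattern (`ExperimentConfig.paper()`).  The package's desk
preset, used by the examples, the test suite and `scripts/acceptance.py`,
runs fewer instance pairs (1–2) with checkpoints {50, 200, 500, 1000, 1500,
2000} and the training-time control at reduced scale (MA at 5000 instead of
10,000 presentations).  These sizes were chosen so a complete desk run
finishes on a single workstation CPU core in minutes rather than days;
between-instance variability is correspondingly larger than in the
full-scale design.

## What the synthetic data does and does not emulate

The word patterns reproduce the study conditions exactly: random, sparse,
independently drawn binary patterns over the two primary areas, shared
within a pair.  They deliberately contain no phonetic structure, no
correlations between words, no semantic (extra-perisylvian) components, and
no articulatory-only or novel-pattern probes.  Passing tests therefore show
that the *architectural* contrast (jumping links vs none) produces the
reported assembly-size, ignition and persistence differences under the
stated learning rule — not that the model generalises to structured speech
material.

## Known limitations

* Eq-level forms of the membrane, adaptation and learning equations are
  reconstructions (the source renders them as images); all are isolated
  behind single functions and configuration flags so a corrected form is a
  one-line change.
* Graded-response pools, no spiking, no conduction delays, no learned
  inhibition, no ventral-pathway projections.
* Quantitative growth-curve values are sensitive to the free couplings
  (w_max, inhibitory gains); only their orderings and qualitative shapes
  are robust across the calibration neighbourhood we explored.
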