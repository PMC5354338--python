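"""Model constants and integration settings.

A single dataclass holds every scalar constant of the graded-response model:
membrane time constants, input/noise scaling, phase-specific global-inhibition
strength, adaptation, the LTP/LTD thresholds of the discretised
Artola-Broecher-Singer learning rule, and the Euler step size.  The defaults
are the published values for this model family; a handful of additional knobs
(synaptic gain, inhibitory gains, weight ceiling, stimulus amplitude) are not
printed anywhere and are documented in docs/methods.md together with the
rationale for their defaults.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Any

import yaml

SQRT48 = math.sqrt(48.0)

#: Canonical phase tags used throughout the package.
TRAIN, TEST = "train", "test"


@dataclasses.dataclass
class ModelParams:
    # --- membrane integration (Eq-1-type leaky integrator) ---
    tau_e: float = 2.5          # excitatory membrane time constant [steps]
    tau_i: float = 5.0          # inhibitory membrane time constant [steps]
    k1: float = 0.01            # input scaling constant
    k2_train: float = 15 * SQRT48   # noise scaling, learning phase
    k2_test: float = 5 * SQRT48     # noise scaling, testing phase
    ks_train: float = 95.0      # area-specific ("global") inhibition, learning
    ks_test: float = 60.0       # area-specific inhibition, testing
    # --- adaptation and gliding averages ---
    alpha: float = 0.026        # adaptation strength (threshold per unit rate)
    tau_A: float = 15.0         # per-cell output average time constant [steps]
    tau_S: float = 8.0          # area-average time constant [steps]
    # --- plasticity thresholds (on postsynaptic potential / pre output) ---
    theta_plus: float = 0.15    # LTP threshold
    theta_minus: float = 0.15   # lower edge of the LTD band
    theta_pre: float = 0.05     # minimum presynaptic output for any change
    delta_w: float = 0.0007     # fixed weight step
    dt: float = 0.5             # Euler step size [arbitrary time units]

    # --- reconstruction / engineering knobs (not in the printed table) ---
    base_threshold: float = 0.0
    #: noise enters the membrane equation as k1*(V_in + k2*eta) when True,
    #: as k1*V_in + k2*eta when False.
    scale_noise_with_input: bool = True
    #: gain applied to the summed synaptic input (excitatory minus inhibitory
    #: minus global-inhibition terms) inside V_in.  The default 1/k1 makes a
    #: unit weight contribute a unit potential, which is required for the
    #: initial weight range [0, 0.1] to conduct stimulus-driven activity.
    synaptic_gain: float = 100.0
    w_max: float = 0.45         # weight ceiling for excitatory plasticity
    w_ei: float = 0.5           # fixed excitatory -> inhibitory link weight
    w_ie: float = 3.5           # fixed inhibitory -> excitatory feedback weight
    stim_amplitude: float = 500.0   # external input per stimulated cell (V_in units)
    #: "band": homosynaptic LTD for theta_minus <= V < theta_plus (ABS rule;
    #: empty band at the default thresholds).  "below": LTD for V < theta_minus.
    homosynaptic_ltd: str = "band"
    heterosynaptic_ltd: bool = True
    ltp: bool = True

    def __post_init__(self) -> None:
        for name in ("tau_e", "tau_i", "tau_A", "tau_S", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.theta_pre <= 1.0):
            raise ValueError("theta_pre must lie in (0, 1]")
        if self.delta_w <= 0 or self.delta_w >= 1:
            raise ValueError("delta_w must lie in (0, 1)")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")
        if self.homosynaptic_ltd not in ("band", "below"):
            raise ValueError("homosynaptic_ltd must be 'band' or 'below'")

    # phase-dependent constants -------------------------------------------
    def k2(self, phase: str) -> float:
        return self.k2_train if phase == TRAIN else self.k2_test

    def ks(self, phase: str) -> float:
        return self.ks_train if phase == TRAIN else self.ks_test

    def noise_gain(self, phase: str) -> float:
        """Multiplier applied to the uniform(-0.5, 0.5) noise draw."""
        k2 = self.k2(phase)
        return self.k1 * k2 if self.scale_noise_with_input else k2

    # (de)serialisation ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)
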