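"""Discretised Artola-Broecher-Singer (ABS) Hebbian rule.

Synaptic changes are two fixed levels, +delta_w and -delta_w, gated by the
presynaptic output and the postsynaptic membrane potential:

* LTP: presynaptic output above ``theta_pre`` and postsynaptic potential at
  or above ``theta_plus``.
* Homosynaptic LTD: presynaptic output above ``theta_pre`` and postsynaptic
  potential in the intermediate band ``[theta_minus, theta_plus)`` -- the ABS
  signature of depression at intermediate depolarisation.  At the default
  parameterisation ``theta_minus == theta_plus`` the band is empty, leaving
  LTP plus heterosynaptic LTD as the active cases; a "below" variant
  (depression for potentials under ``theta_minus``) is available for
  sensitivity analyses.
* Heterosynaptic LTD: presynaptic output at or below ``theta_pre`` while the
  postsynaptic potential is at or above ``theta_plus``.
* Otherwise: no change.

Weights are clipped to [0, ``w_max``] after every update.  Only excitatory
links are plastic.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .connectivity import SynapseSet
from .params import ModelParams


@dataclasses.dataclass(frozen=True)
class PlasticityRule:
    theta_pre: float = 0.05
    theta_plus: float = 0.15
    theta_minus: float = 0.15
    delta_w: float = 0.0007
    w_max: float = 0.45
    homosynaptic_ltd: str = "band"   # "band" (ABS) or "below"
    heterosynaptic_ltd: bool = True
    ltp: bool = True

    def __post_init__(self):
        if not (0.0 < self.theta_pre <= 1.0):
            raise ValueError("theta_pre must lie in (0, 1]")
        if self.delta_w <= 0:
            raise ValueError("delta_w must be positive")
        if self.homosynaptic_ltd not in ("band", "below"):
            raise ValueError("homosynaptic_ltd must be 'band' or 'below'")

    @classmethod
    def from_params(cls, p: ModelParams) -> "PlasticityRule":
        return cls(p.theta_pre, p.theta_plus, p.theta_minus, p.delta_w,
                   p.w_max, p.homosynaptic_ltd, p.heterosynaptic_ltd, p.ltp)


def hebbian_update(w, pre_O, post_V, rule: PlasticityRule):
    """Apply the rule to one link or elementwise to arrays of links.

    Returns the new weight(s), clipped to [0, w_max].  The four cases are
    exhaustive and mutually exclusive for every (pre_O, post_V).
    """
    w = np.asarray(w, dtype=float)
    pre_O = np.asarray(pre_O, dtype=float)
    post_V = np.asarray(post_V, dtype=float)
    active = pre_O > rule.theta_pre
    depol = post_V >= rule.theta_plus
    if rule.homosynaptic_ltd == "band":
        ltd_zone = (post_V >= rule.theta_minus) & ~depol
    else:
        ltd_zone = post_V < rule.theta_minus
    delta = np.zeros(np.broadcast(w, pre_O, post_V).shape)
    if rule.ltp:
        delta += np.where(active & depol, rule.delta_w, 0.0)
    delta -= np.where(active & ltd_zone, rule.delta_w, 0.0)
    if rule.heterosynaptic_ltd:
        delta -= np.where(~active & depol, rule.delta_w, 0.0)
    return np.clip(w + delta, 0.0, rule.w_max)


def apply_plasticity(synapses: SynapseSet, outputs: np.ndarray,
                     potentials: np.ndarray, rule: PlasticityRule) -> SynapseSet:
    """Update every excitatory link from time-t pre output and time-t post
    potential, in place.  Inhibitory wiring is fixed and untouched.  Called
    once per training time step; never during testing."""
    synapses.w[:] = hebbian_update(synapses.w, outputs[synapses.pre],
                                   potentials[synapses.post], rule)
    return synapses
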