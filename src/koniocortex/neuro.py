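"""Single-neuron primitives: activation, plasticity and shunting normalization.

Every quantity that travels between neurons is a firing rate in [0, 1].
Four primitives generate all of the network's behaviour:

* a logistic activation with a movable threshold (the "shift"),
* intrinsic plasticity (IP) that moves the shift,
* the presynaptic learning rule with a weight-dependent LTP threshold
  (metaplasticity), and
* shunting (divisive) normalization of a weighted sum by the l1-norm of the
  thalamocortical output vector.

Intrinsic plasticity comes in two flavours used by different layers.
Thalamocortical neurons track the running average of their own output (the
average neural activity, ANA), which subtracts each input's moving average
and separates overlapping patterns.  Spiny stellate neurons regulate their
firing rate around a homeostatic target: the shift integrates the deviation
of the output from the target rate, which prices persistent winners out of
patterns they should not own and revives silent neurons.  Both flavours move
the shift with the same velocity constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS_L1 = 1e-12  # divisive-normalization guard


@dataclass(frozen=True)
class ActivationParams:
    """Sigmoid steepness and threshold.  ``kind`` may be 'sigmoidal' or 'linear'."""

    k: float = 40.0
    shift: float = 0.061
    kind: str = "sigmoidal"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("steepness k must be positive")
        if not 0.0 <= self.shift <= 1.0:
            raise ValueError("shift must lie in [0, 1]")


@dataclass(frozen=True)
class PlasticityParams:
    """Learning factor, shifting velocity and the ANA averaging constant."""

    xi: float = 0.0019
    upsilon: float = 0.0199
    ana_window: float = 0.0199  # EMA rate constant for the ANA estimate

    def __post_init__(self) -> None:
        if self.xi < 0 or self.upsilon < 0:
            raise ValueError("xi and upsilon must be non-negative")


def sigmoid_activation(net, params: ActivationParams = ActivationParams()):
    """Logistic rate 1 / (1 + exp(-k (net - s))); 0.5 exactly at net = shift."""
    z = np.clip(params.k * (np.asarray(net, dtype=float) - params.shift), -700, 700)
    return 1.0 / (1.0 + np.exp(-z))


def linear_activation(net):
    """Identity on [0, 1], clamped outside so the output is always a rate."""
    return np.clip(net, 0.0, 1.0)


def presynaptic_weight_update(w, pre, post, xi: float):
    """One step of the presynaptic rule:  w += xi * pre * post * (post - w).

    The sign of the change flips where ``post`` crosses the current weight,
    so the LTP threshold grows with w (metaplasticity).  With no presynaptic
    or no postsynaptic activity the weight is untouched; in particular silent
    neurons keep their memories.  The fixed point under sustained activity is
    w* = post.
    """
    w = np.asarray(w, dtype=float)
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if xi < 0:
        raise ValueError("xi must be non-negative")
    for name, arr in (("w", w), ("pre", pre), ("post", post)):
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    return np.clip(w + xi * pre * post * (post - w), 0.0, 1.0)


def ltp_threshold(w):
    """Postsynaptic activity at which the presynaptic rule changes sign."""
    return np.asarray(w, dtype=float)


def update_ana(ana, o, window: float):
    """Exponential moving average of the output: ana += window * (o - ana)."""
    ana = np.asarray(ana, dtype=float)
    return np.clip(ana + window * (np.asarray(o, dtype=float) - ana), 0.0, 1.0)


def ip_shift_update(s, ana, upsilon: float):
    """First-order IP: the shift moves toward the ANA with velocity upsilon.

    Used by thalamocortical neurons, where the shift converging on the
    average output implements moving-average removal of the input pattern.
    """
    s = np.asarray(s, dtype=float)
    return np.clip(s + upsilon * (np.asarray(ana, dtype=float) - s), 0.0, 1.0)


def ip_setpoint_update(s, o, target_rate: float, upsilon: float):
    """Homeostatic IP: the shift integrates the rate deviation from target.

    Used by spiny stellate neurons.  A neuron firing above ``target_rate``
    raises its threshold; one firing below lowers it, down to clamp.  The
    equilibrium duty cycle equals the target rate.
    """
    s = np.asarray(s, dtype=float)
    return np.clip(s + upsilon * (np.asarray(o, dtype=float) - target_rate), 0.0, 1.0)


def shunting_normalize(weighted_sum, tc_outputs, gabaa_on: bool):
    """Divide a weighted sum by the l1-norm of the thalamocortical outputs.

    This is the shunting-basket operation: linear summation of the TC vector
    followed by divisive inhibition of the target's net input.  With GABA-A
    signalling off the division is bypassed and the raw sum passes through.
    The result is invariant to a common positive rescaling of ``weighted_sum``
    and ``tc_outputs``; a vanishing l1-norm yields 0.
    """
    tc_outputs = np.asarray(tc_outputs, dtype=float)
    if np.any(tc_outputs < 0):
        raise ValueError("tc_outputs must be non-negative")
    if not gabaa_on:
        return weighted_sum
    l1 = float(tc_outputs.sum())
    if l1 < EPS_L1:
        return np.zeros_like(np.asarray(weighted_sum, dtype=float)) if np.ndim(weighted_sum) else 0.0
    return np.asarray(weighted_sum, dtype=float) / l1
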