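"""The koniocortex circuit: wiring, state and the single-iteration update.

Five populations are modelled.  Sensory input neurons (I) are forced to the
stimulus.  Thalamocortical neurons (TC) relay the stimulus one-to-one through
a sigmoid whose shift tracks the neuron's average activity (pattern
separation).  One shunting basket unit (SB) sums the TC vector (l1-norm) and
divides the spiny stellate net input (normalization).  Spiny stellate
neurons (SS) receive the weighted TC drive, an autapse, and subtractive
inhibition from the upper basket neurons (B), each of which relays the
output of its spiny cell onto the others.  An ancillary set of virtual
connections from SS back to the input layer learns, for every spiny neuron,
a copy of the pattern that fires it; these are used for recall only.

Within an iteration the spiny layer resolves its competition with an
asynchronous sweep: neurons are updated one at a time in order of distance
to threshold, each seeing the basket activity produced by neurons updated
before it.  This latency ordering is what lets a single leader suppress the
rest of the pool within the iteration; a fully synchronous layer update
instead locks the pool into a symmetric all-fire/all-silent flip-flop in
which no neuron can specialize.  All quantities that cross an iteration
boundary (TC outputs, weights, shifts) follow synchronous semantics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .neuro import EPS_L1

__all__ = [
    "LayerSpec", "ModelParams", "WeightSet", "NetworkState",
    "init_network", "step", "naive_step", "present_pattern", "run_epoch",
    "prune_step", "apply_flag", "save_state", "load_state",
]


@dataclass(frozen=True)
class LayerSpec:
    n_input: int = 15
    n_tc: int = 15
    n_ss: int = 10
    n_basket: int = 10
    n_shunting: int = 1

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_tc, self.n_ss, self.n_basket, self.n_shunting) <= 0:
            raise ValueError("all layer sizes must be positive")
        if self.n_input != self.n_tc:
            raise ValueError("input and TC layers are wired one-to-one")
        if self.n_ss != self.n_basket:
            raise ValueError("each spiny cell drives its own basket neuron")


@dataclass(frozen=True)
class ModelParams:
    """All numeric constants of the circuit.

    ``target_rate`` is the homeostatic firing-rate set point of the spiny
    layer; its default, 1/n_ss, makes the equilibrium duty cycle of every
    spiny neuron exactly one pattern out of the training set of ten.
    """

    k: float = 40.0                 # sigmoid steepness (all sigmoidal neurons)
    xi: float = 0.0019              # learning factor
    upsilon: float = 0.0199         # shifting velocity
    shift_init: float = 0.061       # initial value of every sigmoid shift
    w_i_tc: float = 1.0             # fixed input->TC weight (one-to-one)
    w_autapse: float = 0.85         # fixed SS->SS self-excitation
    w_ss_b: float = 0.98            # fixed SS->basket weight
    w_sb_ss: float = 0.5            # nominal SB->SS constant (divisor gain 1 by default)
    w_b_ss: float = 0.98            # basket->SS subtractive weight (mirrors the SS->B leg)
    sb_divisor_gain: float = 1.0    # gain on the l1-norm divisor
    w_init_max: float = 0.05        # upper bound of "negligible" initial weights
    target_rate: float = 0.1        # homeostatic rate set point of SS neurons
    prune_fraction: float = 0.017   # fraction of surviving synapses per pruning event


@dataclass
class WeightSet:
    w_tc_ss: np.ndarray            # (n_tc, n_ss), modifiable
    w_ss_i: np.ndarray             # (n_ss, n_input), modifiable (ancillary recall)
    prune_mask: np.ndarray         # bool, aligned with w_tc_ss; True = pruned
    frozen: bool = False


@dataclass
class NetworkState:
    spec: LayerSpec
    params: ModelParams
    weights: WeightSet
    o_sensory: np.ndarray
    o_tc: np.ndarray
    o_ss: np.ndarray
    o_basket: np.ndarray
    o_shunting: float
    s_tc: np.ndarray               # TC shifts (IP-bearing)
    s_ss: np.ndarray               # SS shifts (IP-bearing)
    ana_tc: np.ndarray             # TC average neural activity estimate
    gabaa_on: bool = True
    ach_on: bool = True
    iteration: int = 0
    epoch: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(
            spec=self.spec, params=self.params,
            weights=WeightSet(self.weights.w_tc_ss.copy(), self.weights.w_ss_i.copy(),
                              self.weights.prune_mask.copy(), self.weights.frozen),
            o_sensory=self.o_sensory.copy(), o_tc=self.o_tc.copy(),
            o_ss=self.o_ss.copy(), o_basket=self.o_basket.copy(),
            o_shunting=self.o_shunting,
            s_tc=self.s_tc.copy(), s_ss=self.s_ss.copy(), ana_tc=self.ana_tc.copy(),
            gabaa_on=self.gabaa_on, ach_on=self.ach_on,
            iteration=self.iteration, epoch=self.epoch,
        )


def init_network(spec: LayerSpec = LayerSpec(), params: ModelParams = ModelParams(),
                 rng: np.random.Generator | int | None = None) -> NetworkState:
    """Fresh network: negligible random weights, all shifts at ``shift_init``."""
    rng = np.random.default_rng(rng)
    w_tc_ss = rng.uniform(0.0, params.w_init_max, (spec.n_tc, spec.n_ss))
    w_ss_i = rng.uniform(0.0, params.w_init_max, (spec.n_ss, spec.n_input))
    return NetworkState(
        spec=spec, params=params,
        weights=WeightSet(w_tc_ss, w_ss_i, np.zeros_like(w_tc_ss, dtype=bool)),
        o_sensory=np.zeros(spec.n_input), o_tc=np.zeros(spec.n_tc),
        o_ss=np.zeros(spec.n_ss), o_basket=np.zeros(spec.n_basket),
        o_shunting=0.0,
        s_tc=np.full(spec.n_tc, params.shift_init),
        s_ss=np.full(spec.n_ss, params.shift_init),
        ana_tc=np.full(spec.n_tc, params.shift_init),
    )


def _sig(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def step(state: NetworkState, stimulus: np.ndarray) -> NetworkState:
    """Advance the whole system by one iteration (in place; returns state).

    The spiny sweep runs in latency order on the previous iteration's TC
    outputs; TC outputs, weights, shifts and the basket/shunting rates are
    then advanced together.  IP on the TC layer is suppressed when ACh is
    off; weight learning is suppressed when the NMDA blockade flag is set.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.shape != (state.spec.n_input,):
        raise ValueError(f"stimulus must have shape ({state.spec.n_input},)")
    if np.any(stimulus < 0) or np.any(stimulus > 1):
        raise ValueError("stimulus components must lie in [0, 1]")
    p = state.params

    o_tc = state.o_tc
    l1 = float(o_tc.sum())
    drive = state.weights.w_tc_ss.T @ o_tc                     # raw weighted TC drive
    div = p.sb_divisor_gain * l1

    # latency ranking from the pre-sweep state; stable sort = lowest index on ties
    b_pre = np.clip(p.w_ss_b * state.o_ss, 0.0, 1.0)
    pre_net = drive + p.w_autapse * state.o_ss - p.w_b_ss * (b_pre.sum() - b_pre)
    if state.gabaa_on:
        pre_net = pre_net / div if div > EPS_L1 else np.zeros_like(pre_net)
    order = np.argsort(-(pre_net - state.s_ss), kind="stable")

    o_ss = state.o_ss.copy()
    for i in order:
        b = np.clip(p.w_ss_b * o_ss, 0.0, 1.0)
        inh = p.w_b_ss * (b.sum() - b[i])
        raw = drive[i] + p.w_autapse * o_ss[i] - inh
        if state.gabaa_on:
            net = raw / div if div > EPS_L1 else 0.0
        else:
            net = raw
        o_ss[i] = _sig(p.k * (net - state.s_ss[i]))

    new_o_tc = _sig(p.k * (p.w_i_tc * stimulus - state.s_tc))

    if not state.weights.frozen:
        w = state.weights.w_tc_ss
        w += p.xi * o_tc[:, None] * o_ss[None, :] * (o_ss[None, :] - w)
        np.clip(w, 0.0, 1.0, out=w)
        w[state.weights.prune_mask] = 0.0
        v = state.weights.w_ss_i
        v += p.xi * o_ss[:, None] * (stimulus[None, :] - v)
        np.clip(v, 0.0, 1.0, out=v)

    state.ana_tc = np.clip(state.ana_tc + p.upsilon * (new_o_tc - state.ana_tc), 0.0, 1.0)
    if state.ach_on:
        # the shift chases the neuron's own output average with velocity upsilon
        state.s_tc = np.clip(state.s_tc + p.upsilon * (new_o_tc - state.s_tc), 0.0, 1.0)
    state.s_ss = np.clip(state.s_ss + p.upsilon * (o_ss - p.target_rate), 0.0, 1.0)

    state.o_sensory = stimulus.copy()
    state.o_tc = new_o_tc
    state.o_ss = o_ss
    state.o_basket = np.clip(p.w_ss_b * o_ss, 0.0, 1.0)
    state.o_shunting = min(l1, 1.0)      # reported rate; the divisor uses the raw l1
    state.iteration += 1
    return state


def naive_step(state: NetworkState, stimulus: np.ndarray) -> NetworkState:
    """Reference implementation of :func:`step` with plain Python loops.

    Deliberately unvectorized; used as an independent oracle in tests.
    """
    stimulus = [float(x) for x in stimulus]
    p = state.params
    n_tc, n_ss = state.spec.n_tc, state.spec.n_ss

    l1 = sum(float(x) for x in state.o_tc)
    drive = [sum(state.weights.w_tc_ss[j][i] * state.o_tc[j] for j in range(n_tc))
             for i in range(n_ss)]
    div = p.sb_divisor_gain * l1

    def sig(z):
        z = max(-700.0, min(700.0, z))
        import math
        return 1.0 / (1.0 + math.exp(-z))

    b_pre = [min(max(p.w_ss_b * o, 0.0), 1.0) for o in state.o_ss]
    margins = []
    for i in range(n_ss):
        inh = p.w_b_ss * (sum(b_pre) - b_pre[i])
        raw = drive[i] + p.w_autapse * state.o_ss[i] - inh
        if state.gabaa_on:
            net = raw / div if div > EPS_L1 else 0.0
        else:
            net = raw
        margins.append(net - state.s_ss[i])
    order = sorted(range(n_ss), key=lambda i: (-margins[i], i))

    o_ss = [float(x) for x in state.o_ss]
    for i in order:
        b = [min(max(p.w_ss_b * o, 0.0), 1.0) for o in o_ss]
        inh = p.w_b_ss * (sum(b) - b[i])
        raw = drive[i] + p.w_autapse * o_ss[i] - inh
        if state.gabaa_on:
            net = raw / div if div > EPS_L1 else 0.0
        else:
            net = raw
        o_ss[i] = sig(p.k * (net - state.s_ss[i]))

    new_o_tc = [sig(p.k * (p.w_i_tc * stimulus[j] - state.s_tc[j])) for j in range(n_tc)]

    if not state.weights.frozen:
        for j in range(n_tc):
            for i in range(n_ss):
                if state.weights.prune_mask[j][i]:
                    state.weights.w_tc_ss[j][i] = 0.0
                    continue
                w = state.weights.w_tc_ss[j][i]
                w += p.xi * state.o_tc[j] * o_ss[i] * (o_ss[i] - w)
                state.weights.w_tc_ss[j][i] = min(max(w, 0.0), 1.0)
        for i in range(n_ss):
            for j in range(n_tc):
                v = state.weights.w_ss_i[i][j]
                v += p.xi * o_ss[i] * (stimulus[j] - v)
                state.weights.w_ss_i[i][j] = min(max(v, 0.0), 1.0)

    for j in range(n_tc):
        a = state.ana_tc[j] + p.upsilon * (new_o_tc[j] - state.ana_tc[j])
        state.ana_tc[j] = min(max(a, 0.0), 1.0)
        if state.ach_on:
            s = state.s_tc[j] + p.upsilon * (new_o_tc[j] - state.s_tc[j])
            state.s_tc[j] = min(max(s, 0.0), 1.0)
    for i in range(n_ss):
        s = state.s_ss[i] + p.upsilon * (o_ss[i] - p.target_rate)
        state.s_ss[i] = min(max(s, 0.0), 1.0)

    state.o_sensory = np.asarray(stimulus)
    state.o_tc = np.asarray(new_o_tc)
    state.o_ss = np.asarray(o_ss)
    state.o_basket = np.asarray([min(max(p.w_ss_b * o, 0.0), 1.0) for o in o_ss])
    state.o_shunting = min(l1, 1.0)
    state.iteration += 1
    return state


def present_pattern(state: NetworkState, vector: np.ndarray, iterations: int = 8) -> NetworkState:
    """Hold one stimulus at the input for ``iterations`` network iterations."""
    if iterations < 1:
        raise ValueError("iterations must be at least 1")
    for _ in range(iterations):
        step(state, vector)
    return state


def run_epoch(state: NetworkState, schedule, bank, stimulus_divisor: float = 1.0,
              rng: np.random.Generator | None = None):
    """Present every active pattern once; returns (state, summary dict)."""
    from .metrics import average_output, average_shift

    outs, shifts = [], []
    for lab in schedule.epoch_order(rng):
        vec = bank.vector(lab) / stimulus_divisor
        for _ in range(schedule.iterations_per_pattern):
            step(state, vec)
            outs.append(average_output(state))
            shifts.append(average_shift(state))
    state.epoch += 1
    outs = np.asarray(outs)
    shifts = np.asarray(shifts)
    summary = {
        "epoch": state.epoch,
        "avg_output": float(outs.mean()),
        "avg_output_ptp": float(np.ptp(outs)),
        "avg_shift": float(shifts.mean()),
        "avg_shift_ptp": float(np.ptp(shifts)),
    }
    return state, summary


def prune_step(state: NetworkState, fraction: float | None = None) -> NetworkState:
    """Prune the smallest surviving modifiable TC->SS weights permanently.

    ``ceil(fraction * n_surviving)`` synapses with the smallest weights are
    set to zero and masked so that they never relearn.  Ties are broken by
    the lowest flat index.
    """
    fraction = state.params.prune_fraction if fraction is None else fraction
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    mask = state.weights.prune_mask
    surviving = np.flatnonzero(~mask.ravel())
    if surviving.size == 0:
        return state
    n_remove = int(np.ceil(fraction * surviving.size))
    w_flat = state.weights.w_tc_ss.ravel()
    order = np.lexsort((surviving, w_flat[surviving]))   # weight, then index
    doomed = surviving[order[:n_remove]]
    mask.ravel()[doomed] = True
    w_flat[doomed] = 0.0
    return state


_FLAGS = ("gabaa_on", "ach_on", "frozen")


def apply_flag(state: NetworkState, flag: str, value: bool) -> NetworkState:
    """Set one of the lesion flags; takes effect on the next iteration."""
    if flag not in _FLAGS:
        raise ValueError(f"unknown flag {flag!r}; expected one of {_FLAGS}")
    if flag == "frozen":
        state.weights.frozen = bool(value)
    else:
        setattr(state, flag, bool(value))
    return state


# -- checkpointing ------------------------------------------------------------

def save_state(state: NetworkState, path) -> None:
    """Serialize the full state to a single .npz archive (round-trip exact)."""
    meta = {
        "spec": asdict(state.spec), "params": asdict(state.params),
        "gabaa_on": state.gabaa_on, "ach_on": state.ach_on,
        "frozen": state.weights.frozen,
        "iteration": state.iteration, "epoch": state.epoch,
        "o_shunting": state.o_shunting,
    }
    np.savez(
        path, meta=json.dumps(meta),
        w_tc_ss=state.weights.w_tc_ss, w_ss_i=state.weights.w_ss_i,
        prune_mask=state.weights.prune_mask,
        o_sensory=state.o_sensory, o_tc=state.o_tc, o_ss=state.o_ss,
        o_basket=state.o_basket, s_tc=state.s_tc, s_ss=state.s_ss,
        ana_tc=state.ana_tc,
    )


def load_state(path) -> NetworkState:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return NetworkState(
            spec=LayerSpec(**meta["spec"]), params=ModelParams(**meta["params"]),
            weights=WeightSet(z["w_tc_ss"], z["w_ss_i"], z["prune_mask"], meta["frozen"]),
            o_sensory=z["o_sensory"], o_tc=z["o_tc"], o_ss=z["o_ss"],
            o_basket=z["o_basket"], o_shunting=float(meta["o_shunting"]),
            s_tc=z["s_tc"], s_ss=z["s_ss"], ana_tc=z["ana_tc"],
            gabaa_on=meta["gabaa_on"], ach_on=meta["ach_on"],
            iteration=meta["iteration"], epoch=meta["epoch"],
        )
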