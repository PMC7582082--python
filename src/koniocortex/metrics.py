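"""Observables: average output/shift, winner maps, recall, oscillation.

The two summary curves reported for every experiment are the average output
of all modelled neurons (TC, SS, basket and shunting-basket cells; sensory
neurons are excluded because they are forced to the stimulus) and the
average firing threshold (shift) of the IP-bearing neurons (TC and SS; the
basket populations carry no shift).

Hypermetabolism is read off the average-output trace: the energetically
expensive regime is one in which thresholds keep being adjusted up and down
so that the population output swings persistently.  Because the swings occur
at the time scale of single iterations, the detector inspects the
iteration-level trace through a sliding window and asks for a sustained run
of epochs whose window amplitude stays above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkState, step

__all__ = [
    "SimulationLog", "OscillationReport",
    "average_output", "average_shift", "winner_map",
    "recall_matrix", "recall_fidelity", "detect_persistent_oscillation",
]


def average_output(state: NetworkState) -> float:
    """Mean output over TC, SS, basket and shunting-basket neurons."""
    total = (state.o_tc.sum() + state.o_ss.sum() + state.o_basket.sum()
             + state.o_shunting)
    n = state.spec.n_tc + state.spec.n_ss + state.spec.n_basket + state.spec.n_shunting
    return float(total / n)


def average_shift(state: NetworkState) -> float:
    """Mean firing threshold over the IP-bearing neurons (TC and SS)."""
    total = state.s_tc.sum() + state.s_ss.sum()
    return float(total / (state.spec.n_tc + state.spec.n_ss))


def winner_map(state: NetworkState, bank, active_labels, threshold: float = 0.5,
               iterations: int = 8) -> dict[str, int | None]:
    """Probe which spiny neuron fires for each pattern; non-destructive.

    Each pattern is presented for ``iterations`` iterations on a copy of the
    state with both learning and threshold adaptation frozen, so that the
    measurement does not perturb the experiment.  A label maps to a spiny
    index only when exactly one neuron's mean output over the presentation
    exceeds ``threshold``; otherwise it maps to ``None``.
    """
    result: dict[str, int | None] = {}
    for lab in active_labels:
        probe = state.copy()
        probe.weights.frozen = True
        s_tc, s_ss, ana = probe.s_tc.copy(), probe.s_ss.copy(), probe.ana_tc.copy()
        acc = np.zeros(state.spec.n_ss)
        for _ in range(iterations):
            step(probe, bank.vector(lab))
            probe.s_tc, probe.s_ss, probe.ana_tc = s_tc.copy(), s_ss.copy(), ana.copy()
            acc += probe.o_ss
        mean = acc / iterations
        above = np.flatnonzero(mean > threshold)
        result[lab] = int(above[0]) if above.size == 1 else None
    return result


def recall_matrix(state: NetworkState, ss_index: int) -> np.ndarray:
    """The pattern evoked by one spiny neuron: its ancillary weight row, as a grid."""
    if not 0 <= ss_index < state.spec.n_ss:
        raise IndexError(f"ss_index must be in [0, {state.spec.n_ss - 1}]")
    return state.weights.w_ss_i[ss_index].reshape(5, 3)


def recall_fidelity(matrix: np.ndarray, target_vector: np.ndarray) -> float:
    """Cosine similarity between an evoked pattern and a bank pattern."""
    a = np.asarray(matrix, dtype=float).ravel()
    b = np.asarray(target_vector, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("shapes do not match")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


@dataclass
class SimulationLog:
    """Per-epoch curves plus snapshots collected during an experiment."""

    epochs_total: int
    avg_output: np.ndarray          # per-epoch mean of the iteration trace
    avg_shift: np.ndarray
    avg_output_iter: np.ndarray     # iteration-level trace (epochs * iters/epoch)
    avg_shift_iter: np.ndarray
    iters_per_epoch: int
    markers: dict[str, int] = field(default_factory=dict)      # intervention -> epoch
    winner_maps: dict[int, dict] = field(default_factory=dict)  # epoch -> label map
    recall_snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    replaced_label: str | None = None

    def to_frame(self):
        import pandas as pd

        epoch_ptp = self.avg_output_iter.reshape(self.epochs_total, -1)
        shift_ptp = self.avg_shift_iter.reshape(self.epochs_total, -1)
        return pd.DataFrame({
            "epoch": np.arange(1, self.epochs_total + 1),
            "avg_output": self.avg_output,
            "avg_shift": self.avg_shift,
            "avg_output_ptp": np.ptp(epoch_ptp, axis=1),
            "avg_shift_ptp": np.ptp(shift_ptp, axis=1),
        })


@dataclass
class OscillationReport:
    intervals: list[tuple[int, int, float]]   # (start epoch, end epoch, mean amplitude)
    persistent: bool
    onset_epoch: int | None

    def __post_init__(self) -> None:
        starts = [a for a, _, _ in self.intervals]
        if starts != sorted(starts):
            raise ValueError("intervals must be ordered")


def detect_persistent_oscillation(
    series: np.ndarray,
    samples_per_epoch: int,
    window_epochs: int = 1,
    amp_threshold: float = 0.2,
    persistence_epochs: int = 100,
    min_interval_epochs: int = 5,
) -> OscillationReport:
    """Flag persistent oscillation in an average-output trace.

    ``series`` is sampled ``samples_per_epoch`` times per epoch (the
    iteration-level trace).  For every epoch the peak-to-peak amplitude of a
    sliding window of ``window_epochs`` epochs is computed; an epoch is
    oscillatory when that amplitude reaches ``amp_threshold`` and the window
    crosses its own mean at least twice.  Maximal oscillatory runs at least
    ``min_interval_epochs`` long are reported as intervals; the verdict is
    persistent when some run reaches ``persistence_epochs``.
    """
    series = np.asarray(series, dtype=float)
    win = window_epochs * samples_per_epoch
    if series.size < win:
        raise ValueError("series shorter than the detection window")
    n_epochs = series.size // samples_per_epoch

    osc = np.zeros(n_epochs, dtype=bool)
    amp = np.zeros(n_epochs)
    for e in range(n_epochs):
        lo = max(0, (e + 1) * samples_per_epoch - win)
        seg = series[lo:(e + 1) * samples_per_epoch]
        a = float(np.ptp(seg))
        amp[e] = a
        if a >= amp_threshold:
            centred = seg - seg.mean()
            crossings = int(np.count_nonzero(np.diff(np.signbit(centred))))
            osc[e] = crossings >= 2

    intervals: list[tuple[int, int, float]] = []
    start = None
    for e in range(n_epochs + 1):
        active = e < n_epochs and osc[e]
        if active and start is None:
            start = e
        elif not active and start is not None:
            if e - start >= min_interval_epochs:
                intervals.append((start, e, float(amp[start:e].mean())))
            start = None

    persistent = any(b - a >= persistence_epochs for a, b, _ in intervals)
    onset = None
    for a, b, _ in intervals:
        if b - a >= persistence_epochs:
            onset = a
            break
    return OscillationReport(intervals=intervals, persistent=persistent, onset_epoch=onset)
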