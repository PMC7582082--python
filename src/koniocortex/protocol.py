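"""Experiment presets and the intervention scheduler.

An experiment is a list of timed interventions over a life span of (by
default) 2,000 epochs.  Interventions are specified as percentages of the
total epoch count and fire at epoch boundaries, before that epoch's
presentations:

* ``gabaa_off`` / ``gabaa_restore`` - remove / reinstate the divisive
  normalization performed by the shunting basket population,
* ``ach_off`` - freeze thalamocortical threshold adaptation (shifting
  velocity set to zero in TC neurons),
* ``stimulus_reduction`` - divide every stimulus component (default by 2)
  persistently from the start epoch onward,
* ``stm_substitution`` - replace one digit (random, or forced) with 'X',
* ``memantine_on`` - freeze all modifiable weights (NMDA blockade),
* ``pruning_start`` - begin periodic removal of the weakest synapses.

The twelve presets named a1..d1 plus ``demo`` reproduce the standard
test battery; ``demo`` is a 1,000-epoch physiological run in which
pattern '1' is forcibly replaced by 'X' at 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import (LayerSpec, ModelParams, init_network, apply_flag,
                      prune_step)
from .patterns import PatternBank, PresentationSchedule, make_pattern_bank, substitute_pattern
from .metrics import SimulationLog, winner_map, detect_persistent_oscillation

__all__ = ["Intervention", "ExperimentSpec", "preset", "PRESET_NAMES",
           "run_experiment", "run_grid"]

KINDS = ("gabaa_off", "gabaa_restore", "ach_off", "stimulus_reduction",
         "stm_substitution", "memantine_on", "pruning_start")


@dataclass(frozen=True)
class Intervention:
    kind: str
    at_pct: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if not 0.0 <= self.at_pct <= 100.0:
            raise ValueError("at_pct must lie in [0, 100]")

    def epoch(self, epochs_total: int) -> int:
        return int(round(self.at_pct / 100.0 * epochs_total))


@dataclass(frozen=True)
class ExperimentSpec:
    name: str
    epochs_total: int = 2000
    interventions: tuple[Intervention, ...] = ()
    n_repeats: int = 20
    forced_stm_label: str | None = None

    def __post_init__(self) -> None:
        kinds = [iv.kind for iv in self.interventions]
        for kind in set(kinds):
            if kind not in ("gabaa_off", "gabaa_restore") and kinds.count(kind) > 1:
                raise ValueError(f"intervention {kind!r} scheduled more than once")


_TABLE = {
    # name: (gabaa_off, gabaa_restore, ach_off, pruning, s_r, stm, mem) in % or None
    "a1": (None, None, None, 75, None, 70, None),
    "a2": (None, None, None, 75, 60, 70, None),
    "b1": (50, None, None, 75, None, None, None),
    "b2": (50, None, None, 75, 60, None, None),
    "b3": (50, None, None, 75, 60, 70, None),
    "b4": (50, None, None, 75, 60, 70, 55),
    "c1": (None, None, 50, 75, None, None, None),
    "c2": (None, None, 50, 75, 60, None, None),
    "c3": (None, None, 50, 75, 60, 70, None),
    "c4": (None, None, 50, 75, 60, 70, 55),
    "d1": (50, 75, None, 75, 60, 85, None),
}

PRESET_NAMES = tuple(_TABLE) + ("demo",)


def preset(name: str) -> ExperimentSpec:
    """Return one of the named experiment presets."""
    if name == "demo":
        return ExperimentSpec(
            name=name, epochs_total=1000,
            interventions=(Intervention("stm_substitution", 50.0),),
            forced_stm_label="1",
        )
    if name not in _TABLE:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    g_off, g_on, ach, prune, s_r, stm, mem = _TABLE[name]
    ivs = []
    if g_off is not None:
        ivs.append(Intervention("gabaa_off", g_off))
    if g_on is not None:
        ivs.append(Intervention("gabaa_restore", g_on))
    if ach is not None:
        ivs.append(Intervention("ach_off", ach))
    if mem is not None:
        ivs.append(Intervention("memantine_on", mem))
    if s_r is not None:
        ivs.append(Intervention("stimulus_reduction", s_r, {"divisor": 2.0}))
    if stm is not None:
        ivs.append(Intervention("stm_substitution", stm))
    if prune is not None:
        ivs.append(Intervention("pruning_start", prune))
    ivs.sort(key=lambda iv: iv.at_pct)
    return ExperimentSpec(name=name, interventions=tuple(ivs))


def _seed_streams(seed: int):
    """Independent child seeds for weight init and the STM label draw."""
    ss = np.random.SeedSequence(seed)
    init_seed, stm_seed = ss.spawn(2)
    return np.random.default_rng(init_seed), np.random.default_rng(stm_seed)


def run_experiment(
    spec: ExperimentSpec,
    bank: PatternBank | None = None,
    params: ModelParams = ModelParams(),
    seed: int = 0,
    layer_spec: LayerSpec = LayerSpec(),
    snapshot_pcts: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100),
    prune_cadence_pct: float = 1.0,
    use_fast: bool = True,
):
    """Run one experiment end to end; returns (SimulationLog, final state, schedule).

    Interventions fire at epoch boundaries.  Pruning repeats every
    ``prune_cadence_pct`` percent of the total epochs from its start epoch.
    Fully reproducible for a given (spec, seed).
    """
    bank = make_pattern_bank() if bank is None else bank
    rng_init, rng_stm = _seed_streams(seed)
    state = init_network(layer_spec, params, rng_init)
    schedule = PresentationSchedule(epochs_total=spec.epochs_total)

    by_epoch: dict[int, list[Intervention]] = {}
    for iv in spec.interventions:
        by_epoch.setdefault(iv.epoch(spec.epochs_total), []).append(iv)
    snap_epochs = {int(round(pct / 100.0 * spec.epochs_total)): pct for pct in snapshot_pcts}
    prune_every = max(1, int(round(prune_cadence_pct / 100.0 * spec.epochs_total)))
    pruning_from: int | None = None

    iters_epoch = schedule.iterations_per_epoch
    avg_out = np.empty(spec.epochs_total * iters_epoch)
    avg_shf = np.empty(spec.epochs_total * iters_epoch)
    markers: dict[str, int] = {}
    winner_maps: dict[int, dict] = {}
    recall_snaps: dict[int, np.ndarray] = {}
    divisor = 1.0

    if use_fast:
        from ._fast import run_epoch_kernel
    else:
        run_epoch_kernel = None

    for e in range(spec.epochs_total):
        for iv in by_epoch.get(e, ()):
            markers[iv.kind] = e
            if iv.kind == "gabaa_off":
                apply_flag(state, "gabaa_on", False)
            elif iv.kind == "gabaa_restore":
                apply_flag(state, "gabaa_on", True)
            elif iv.kind == "ach_off":
                apply_flag(state, "ach_on", False)
            elif iv.kind == "memantine_on":
                apply_flag(state, "frozen", True)
            elif iv.kind == "stimulus_reduction":
                divisor = float(iv.params.get("divisor", 2.0))
            elif iv.kind == "stm_substitution":
                schedule = substitute_pattern(schedule, rng_stm, spec.forced_stm_label)
            elif iv.kind == "pruning_start":
                pruning_from = e
        if pruning_from is not None and (e - pruning_from) % prune_every == 0:
            prune_step(state)

        lo = e * iters_epoch
        stimuli = bank.matrix(schedule.active_labels) / divisor
        if run_epoch_kernel is not None:
            p = state.params
            run_epoch_kernel(
                state.weights.w_tc_ss, state.weights.w_ss_i, state.weights.prune_mask,
                state.o_tc, state.o_ss, state.s_tc, state.s_ss, state.ana_tc,
                stimuli, schedule.iterations_per_pattern,
                p.k, p.xi, p.upsilon, p.target_rate,
                p.w_i_tc, p.w_autapse, p.w_ss_b, p.w_b_ss, p.sb_divisor_gain,
                state.gabaa_on, state.ach_on, state.weights.frozen,
                avg_out[lo:lo + iters_epoch], avg_shf[lo:lo + iters_epoch],
            )
            state.o_basket = np.clip(state.params.w_ss_b * state.o_ss, 0.0, 1.0)
            state.o_shunting = min(float(state.o_tc.sum()), 1.0)
            state.iteration += iters_epoch
            state.epoch += 1
        else:
            from .network import run_epoch as _slow_epoch
            from .metrics import average_output, average_shift
            from .network import step as _step
            k = lo
            for lab in schedule.active_labels:
                vec = bank.vector(lab) / divisor
                for _ in range(schedule.iterations_per_pattern):
                    _step(state, vec)
                    avg_out[k] = average_output(state)
                    avg_shf[k] = average_shift(state)
                    k += 1
            state.epoch += 1

        if e + 1 in snap_epochs:
            winner_maps[e + 1] = winner_map(state, bank, schedule.active_labels)
            recall_snaps[e + 1] = state.weights.w_ss_i.copy()

    epoch_view = avg_out.reshape(spec.epochs_total, iters_epoch)
    shift_view = avg_shf.reshape(spec.epochs_total, iters_epoch)
    log = SimulationLog(
        epochs_total=spec.epochs_total,
        avg_output=epoch_view.mean(axis=1),
        avg_shift=shift_view.mean(axis=1),
        avg_output_iter=avg_out,
        avg_shift_iter=avg_shf,
        iters_per_epoch=iters_epoch,
        markers=markers,
        winner_maps=winner_maps,
        recall_snapshots=recall_snaps,
        replaced_label=schedule.replaced_label,
    )
    return log, state, schedule


def run_grid(specs, seeds, bank: PatternBank | None = None,
             params: ModelParams = ModelParams(), **kwargs):
    """Run every (spec, seed) pair; returns a tidy table with verdicts.

    The returned DataFrame has one row per run (preset, seed, persistent
    flag, onset epoch, X winner if an STM task ran) plus, via
    ``df.attrs['summary']``, the fraction of seeds with a hypermetabolism
    verdict per preset.
    """
    import pandas as pd

    specs = list(specs)
    seeds = list(seeds)
    if not specs or not seeds:
        raise ValueError("specs and seeds must be non-empty")
    rows = []
    for spec in specs:
        for seed in seeds:
            log, state, schedule = run_experiment(spec, bank=bank, params=params,
                                                  seed=seed, **kwargs)
            report = detect_persistent_oscillation(
                log.avg_output_iter, samples_per_epoch=log.iters_per_epoch)
            wm = log.winner_maps.get(spec.epochs_total, {})
            rows.append({
                "preset": spec.name, "seed": seed,
                "persistent": report.persistent,
                "onset_epoch": report.onset_epoch,
                "n_intervals": len(report.intervals),
                "x_winner": wm.get("X"),
                "replaced_label": log.replaced_label,
            })
    df = pd.DataFrame(rows)
    df.attrs["summary"] = df.groupby("preset")["persistent"].mean().to_dict()
    return df
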