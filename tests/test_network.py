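import numpy as np
import pytest

import koniocortex as kc
from koniocortex.network import naive_step

from conftest import random_state


class TestInit:
    def test_seeded_inits_are_identical(self):
        a = kc.init_network(rng=42)
        b = kc.init_network(rng=42)
        assert np.array_equal(a.weights.w_tc_ss, b.weights.w_tc_ss)
        assert np.array_equal(a.weights.w_ss_i, b.weights.w_ss_i)

    def test_initial_shifts(self, fresh_state):
        assert np.all(fresh_state.s_tc == 0.061)
        assert np.all(fresh_state.s_ss == 0.061)

    def test_initial_weights_are_negligible(self, fresh_state):
        assert fresh_state.weights.w_tc_ss.max() <= 0.05
        assert fresh_state.weights.w_ss_i.max() <= 0.05

    def test_layer_spec_validation(self):
        with pytest.raises(ValueError):
            kc.LayerSpec(n_input=15, n_tc=14)
        with pytest.raises(ValueError):
            kc.LayerSpec(n_ss=10, n_basket=9)


class TestStep:
    def test_zero_stimulus_keeps_spiny_layer_below_half(self, fresh_state):
        kc.step(fresh_state, np.zeros(15))
        assert np.all(fresh_state.o_ss < 0.5)

    def test_malformed_stimulus_rejected(self, fresh_state):
        with pytest.raises(ValueError):
            kc.step(fresh_state, np.zeros(14))
        with pytest.raises(ValueError):
            kc.step(fresh_state, np.full(15, 1.5))

    def test_frozen_weights_are_bit_identical(self, bank, fresh_state):
        kc.apply_flag(fresh_state, "frozen", True)
        before_w = fresh_state.weights.w_tc_ss.copy()
        before_v = fresh_state.weights.w_ss_i.copy()
        for lab in "0123":
            kc.present_pattern(fresh_state, bank.vector(lab), 8)
        assert np.array_equal(fresh_state.weights.w_tc_ss, before_w)
        assert np.array_equal(fresh_state.weights.w_ss_i, before_v)

    def test_normalized_drive_invariant_to_tc_scaling(self, fresh_state):
        # the drive term of the spiny net input only depends on the direction
        # of the TC output vector while normalization is on
        state = fresh_state
        rng = np.random.default_rng(3)
        state.o_tc[:] = rng.uniform(0.1, 1.0, 15)
        drive1 = kc.shunting_normalize(state.weights.w_tc_ss.T @ state.o_tc,
                                       state.o_tc, True)
        state.o_tc *= 0.5
        drive2 = kc.shunting_normalize(state.weights.w_tc_ss.T @ state.o_tc,
                                       state.o_tc, True)
        assert np.allclose(drive1, drive2)
        # and with GABA-A off the same halving halves the drive
        state.o_tc *= 2.0
        raw1 = kc.shunting_normalize(state.weights.w_tc_ss.T @ state.o_tc,
                                     state.o_tc, False)
        state.o_tc *= 0.5
        raw2 = kc.shunting_normalize(state.weights.w_tc_ss.T @ state.o_tc,
                                     state.o_tc, False)
        assert np.allclose(raw2, raw1 * 0.5)

    def test_spiny_responses_diversify_over_a_presentation(self, bank):
        # after one iteration the fresh spiny layer responds uniformly; by the
        # eighth the weighted drive and lateral inhibition have separated it
        one_iter = kc.init_network(rng=1)
        kc.step(one_iter, bank.vector("3"))
        eight = kc.init_network(rng=1)
        kc.present_pattern(eight, bank.vector("3"), 8)
        assert eight.o_tc.max() > 0.9              # the stimulus reached TC
        assert eight.o_ss.std() > 3 * one_iter.o_ss.std()

    def test_iteration_counter(self, bank, fresh_state):
        kc.present_pattern(fresh_state, bank.vector("0"), 8)
        assert fresh_state.iteration == 8
        with pytest.raises(ValueError):
            kc.present_pattern(fresh_state, bank.vector("0"), 0)


class TestNaiveOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_production_step_matches_loop_reference(self, seed, bank):
        rng = np.random.default_rng(seed)
        a = random_state(rng)
        b = a.copy()
        stim = bank.vector(str(seed % 10))
        kc.step(a, stim)
        naive_step(b, stim)
        for x, y in [(a.o_tc, b.o_tc), (a.o_ss, b.o_ss),
                     (a.s_tc, b.s_tc), (a.s_ss, b.s_ss),
                     (a.weights.w_tc_ss, b.weights.w_tc_ss),
                     (a.weights.w_ss_i, b.weights.w_ss_i)]:
            assert np.allclose(x, y, atol=1e-12)

    def test_fast_kernel_matches_python_step(self, bank):
        from koniocortex._fast import run_epoch_kernel

        a = kc.init_network(rng=11)
        b = a.copy()
        sched = kc.PresentationSchedule(epochs_total=3)
        stimuli = bank.matrix(sched.active_labels)
        out = np.empty(80); shf = np.empty(80)
        p = a.params
        run_epoch_kernel(a.weights.w_tc_ss, a.weights.w_ss_i, a.weights.prune_mask,
                         a.o_tc, a.o_ss, a.s_tc, a.s_ss, a.ana_tc,
                         stimuli, 8, p.k, p.xi, p.upsilon, p.target_rate,
                         p.w_i_tc, p.w_autapse, p.w_ss_b, p.w_b_ss, p.sb_divisor_gain,
                         True, True, False, out, shf)
        outs_py = []
        for lab in sched.active_labels:
            for _ in range(8):
                kc.step(b, bank.vector(lab))
                outs_py.append(kc.average_output(b))
        assert np.allclose(a.o_ss, b.o_ss, atol=1e-12)
        assert np.allclose(a.weights.w_tc_ss, b.weights.w_tc_ss, atol=1e-12)
        assert np.allclose(a.s_ss, b.s_ss, atol=1e-12)
        assert np.allclose(out, outs_py, atol=1e-12)


class TestBounds:
    def test_no_quantity_leaves_unit_interval_long_run(self, bank):
        # 100k random-stimulus iterations through the compiled kernel,
        # toggling the lesion flags along the way
        from koniocortex._fast import run_epoch_kernel

        state = kc.init_network(rng=9)
        rng = np.random.default_rng(9)
        p = state.params
        for chunk in range(10):
            stimuli = rng.uniform(0, 1, (125, 15))
            out = np.empty(125 * 8); shf = np.empty(125 * 8)
            run_epoch_kernel(state.weights.w_tc_ss, state.weights.w_ss_i,
                             state.weights.prune_mask,
                             state.o_tc, state.o_ss, state.s_tc, state.s_ss,
                             state.ana_tc, stimuli, 8,
                             p.k, p.xi, p.upsilon, p.target_rate,
                             p.w_i_tc, p.w_autapse, p.w_ss_b, p.w_b_ss,
                             p.sb_divisor_gain,
                             chunk % 2 == 0, chunk % 3 != 0, chunk % 4 == 0,
                             out, shf)
            for arr in (state.o_tc, state.o_ss, state.s_tc, state.s_ss,
                        state.ana_tc, state.weights.w_tc_ss, state.weights.w_ss_i):
                assert arr.min() >= 0.0 and arr.max() <= 1.0


class TestPrune:
    def _trained_weights(self):
        state = kc.init_network(rng=2)
        state.weights.w_tc_ss[:] = np.random.default_rng(2).uniform(0, 1, (15, 10))
        return state

    def test_ceil_rule(self):
        state = self._trained_weights()
        kc.prune_step(state, 0.017)   # ceil(0.017 * 150) = 3
        assert state.weights.prune_mask.sum() == 3

    def test_selection_property(self):
        state = self._trained_weights()
        w_before = state.weights.w_tc_ss.copy()
        kc.prune_step(state, 0.2)
        mask = state.weights.prune_mask
        assert w_before[mask].max() <= w_before[~mask].min()
        assert np.all(state.weights.w_tc_ss[mask] == 0.0)

    def test_pruned_synapses_never_relearn(self, bank):
        state = self._trained_weights()
        kc.prune_step(state, 0.2)
        mask = state.weights.prune_mask.copy()
        for lab in "0123456789":
            kc.present_pattern(state, bank.vector(lab), 8)
        assert np.all(state.weights.w_tc_ss[mask] == 0.0)

    def test_all_pruned_is_noop(self):
        state = self._trained_weights()
        state.weights.prune_mask[:] = True
        kc.prune_step(state, 0.5)   # nothing left to remove
        assert state.weights.prune_mask.all()

    def test_bad_fraction_rejected(self, fresh_state):
        with pytest.raises(ValueError):
            kc.prune_step(fresh_state, 0.0)


class TestFlags:
    def test_unknown_flag_rejected(self, fresh_state):
        with pytest.raises(ValueError):
            kc.apply_flag(fresh_state, "nmda_on", True)

    def test_ach_off_freezes_tc_shifts(self, bank, fresh_state):
        kc.apply_flag(fresh_state, "ach_on", False)
        before = fresh_state.s_tc.copy()
        kc.present_pattern(fresh_state, bank.vector("5"), 8)
        assert np.array_equal(fresh_state.s_tc, before)
        assert not np.array_equal(fresh_state.s_ss, np.full(10, 0.061))

    def test_freeze_round_trip_restores_learning(self, bank, fresh_state):
        kc.apply_flag(fresh_state, "frozen", True)
        w0 = fresh_state.weights.w_tc_ss.copy()
        kc.present_pattern(fresh_state, bank.vector("5"), 8)
        assert np.array_equal(fresh_state.weights.w_tc_ss, w0)
        kc.apply_flag(fresh_state, "frozen", False)
        kc.present_pattern(fresh_state, bank.vector("5"), 8)
        assert not np.array_equal(fresh_state.weights.w_tc_ss, w0)


class TestCheckpoint:
    def test_round_trip_exact(self, bank, tmp_path, fresh_state):
        kc.present_pattern(fresh_state, bank.vector("7"), 8)
        kc.apply_flag(fresh_state, "gabaa_on", False)
        path = tmp_path / "state.npz"
        kc.save_state(fresh_state, path)
        again = kc.load_state(path)
        assert np.array_equal(again.weights.w_tc_ss, fresh_state.weights.w_tc_ss)
        assert np.array_equal(again.s_ss, fresh_state.s_ss)
        assert again.gabaa_on is False
        assert again.iteration == fresh_state.iteration
        # the reloaded state continues identically
        a, b = fresh_state, again
        kc.step(a, bank.vector("1")); kc.step(b, bank.vector("1"))
        assert np.array_equal(a.o_ss, b.o_ss)
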