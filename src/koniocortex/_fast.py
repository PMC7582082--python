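"""Compiled epoch kernel.

A numba translation of :func:`koniocortex.network.step`, run for a whole
epoch at a time.  The Python step is the reference; a test asserts that one
epoch through this kernel reproduces it to floating-point accuracy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EPS_L1 = 1e-12


@njit(cache=True)
def _sig(z):
    if z > 700.0:
        z = 700.0
    elif z < -700.0:
        z = -700.0
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True)
def run_epoch_kernel(
    w_tc_ss, w_ss_i, prune_mask,
    o_tc, o_ss, s_tc, s_ss, ana_tc,
    stimuli,                 # (n_patterns, n_input) already intensity-scaled
    iters_per_pattern,
    k, xi, upsilon, target_rate,
    w_i_tc, w_autapse, w_ss_b, w_b_ss, sb_divisor_gain,
    gabaa_on, ach_on, frozen,
    out_avg_output, out_avg_shift,   # (n_patterns*iters,) iteration-level traces
):
    n_tc, n_ss = w_tc_ss.shape
    n_pat = stimuli.shape[0]
    n_neur = float(n_tc + n_ss + n_ss + 1)       # TC + SS + B + SB
    n_ip = float(n_tc + n_ss)
    t = 0
    for pidx in range(n_pat):
        stim = stimuli[pidx]
        for _ in range(iters_per_pattern):
            l1 = 0.0
            for j in range(n_tc):
                l1 += o_tc[j]
            div = sb_divisor_gain * l1

            drive = np.empty(n_ss)
            for i in range(n_ss):
                acc = 0.0
                for j in range(n_tc):
                    acc += w_tc_ss[j, i] * o_tc[j]
                drive[i] = acc

            # latency ranking from the pre-sweep state (stable on ties)
            b_sum = 0.0
            b_pre = np.empty(n_ss)
            for i in range(n_ss):
                b = w_ss_b * o_ss[i]
                if b > 1.0:
                    b = 1.0
                elif b < 0.0:
                    b = 0.0
                b_pre[i] = b
                b_sum += b
            margin = np.empty(n_ss)
            for i in range(n_ss):
                raw = drive[i] + w_autapse * o_ss[i] - w_b_ss * (b_sum - b_pre[i])
                if gabaa_on:
                    net = raw / div if div > EPS_L1 else 0.0
                else:
                    net = raw
                margin[i] = -(net - s_ss[i])
            order = np.argsort(margin, kind="mergesort")

            for oi in range(n_ss):
                i = order[oi]
                bs = 0.0
                bi = 0.0
                for j in range(n_ss):
                    b = w_ss_b * o_ss[j]
                    if b > 1.0:
                        b = 1.0
                    elif b < 0.0:
                        b = 0.0
                    bs += b
                    if j == i:
                        bi = b
                raw = drive[i] + w_autapse * o_ss[i] - w_b_ss * (bs - bi)
                if gabaa_on:
                    net = raw / div if div > EPS_L1 else 0.0
                else:
                    net = raw
                o_ss[i] = _sig(k * (net - s_ss[i]))

            new_o_tc = np.empty(n_tc)
            for j in range(n_tc):
                new_o_tc[j] = _sig(k * (w_i_tc * stim[j] - s_tc[j]))

            if not frozen:
                for j in range(n_tc):
                    pre = o_tc[j]
                    for i in range(n_ss):
                        if prune_mask[j, i]:
                            w_tc_ss[j, i] = 0.0
                            continue
                        w = w_tc_ss[j, i] + xi * pre * o_ss[i] * (o_ss[i] - w_tc_ss[j, i])
                        if w > 1.0:
                            w = 1.0
                        elif w < 0.0:
                            w = 0.0
                        w_tc_ss[j, i] = w
                for i in range(n_ss):
                    pre = o_ss[i]
                    for j in range(n_tc):
                        v = w_ss_i[i, j] + xi * pre * (stim[j] - w_ss_i[i, j])
                        if v > 1.0:
                            v = 1.0
                        elif v < 0.0:
                            v = 0.0
                        w_ss_i[i, j] = v

            shift_sum = 0.0
            for j in range(n_tc):
                a = ana_tc[j] + upsilon * (new_o_tc[j] - ana_tc[j])
                ana_tc[j] = 0.0 if a < 0.0 else (1.0 if a > 1.0 else a)
                if ach_on:
                    s = s_tc[j] + upsilon * (new_o_tc[j] - s_tc[j])
                    s_tc[j] = 0.0 if s < 0.0 else (1.0 if s > 1.0 else s)
                shift_sum += s_tc[j]
            for i in range(n_ss):
                s = s_ss[i] + upsilon * (o_ss[i] - target_rate)
                s_ss[i] = 0.0 if s < 0.0 else (1.0 if s > 1.0 else s)
                shift_sum += s_ss[i]

            for j in range(n_tc):
                o_tc[j] = new_o_tc[j]

            out_sum = 0.0
            for j in range(n_tc):
                out_sum += o_tc[j]
            sb = l1 if l1 < 1.0 else 1.0
            # note: l1 here is the *previous* iteration's TC sum, matching step()
            for i in range(n_ss):
                b = w_ss_b * o_ss[i]
                if b > 1.0:
                    b = 1.0
                elif b < 0.0:
                    b = 0.0
                out_sum += o_ss[i] + b
            out_sum += sb
            out_avg_output[t] = out_sum / n_neur
            out_avg_shift[t] = shift_sum / n_ip
            t += 1
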