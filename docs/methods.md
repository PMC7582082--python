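# Methods

## Model overview

The package simulates a single koniocortex column as a discrete-time,
rate-based network. Every neuron communicates a firing rate in [0, 1]; one
*iteration* updates all outputs, weights and thresholds once, and one
*epoch* presents the complete active pattern set, each pattern held at the
input for 8 consecutive iterations (10 patterns × 8 = 80 iterations per
epoch). The life span of a standard experiment is 2,000 epochs; the
physiological demonstration uses 1,000.

Layer sizes are fixed by the modelled circuit: 15 sensory inputs (the 5×3
pixel grid), 15 thalamocortical (TC) relays, 10 spiny stellate (SS) cells,
10 basket (B) cells and one shunting basket (SB) unit. The SB unit pools
all 15 TC outputs; a single unit realizes the l1-norm divisor exactly.

### Activation

All sigmoidal neurons use the logistic `o = 1/(1 + exp(-k(net − s)))` with
steepness `k = 40` and a movable threshold (*shift*) `s ∈ [0, 1]`. Basket
activation is linear, clamped to [0, 1] so every transmitted value is a
rate. The SB unit's divisive signal is the raw l1-norm (clamping it would
break the exact scale invariance of the normalization); its *reported* rate
in the average-output metric is the clamped value.

### Intrinsic plasticity (two modes)

Intrinsic plasticity adjusts each threshold with velocity `υ = 0.0199`, in
one of two modes:

* **TC neurons — average tracking.** `s ← s + υ(o − s)`: the shift is an
  exponential moving average of the neuron's own output. Because the
  threshold sits at each pixel's long-run activity, the relay subtracts
  every input's moving average — the pattern-separation operation. Under
  full binary stimuli this leaves TC outputs crisply binary; when stimuli
  are halved, thresholds of frequently active pixels approach the new pixel
  value (0.5) and the relay's responses become fragile. This is the locus
  where stimulus reduction bites.
* **SS neurons — homeostatic set point.** `s ← s + υ(o − a₀)` with target
  rate `a₀ = 1/n_SS = 0.1`: the shift integrates the deviation of the
  firing rate from a homeostatic target. A neuron owning more than one
  pattern fires above target and is priced out of its weakest pattern; a
  silent neuron's threshold decays until it can fire again. The equilibrium
  duty cycle of every spiny cell is exactly one pattern in ten, which is
  what makes the ten-to-ten winner assignment an attractor.

The two modes are two faces of the same homeostatic principle (threshold
follows activity); they differ in what the threshold is asked to track. A
single first-order "shift chases the output average" rule at the SS layer
cannot produce sparse competition: a threshold expressed in *output* units
necessarily sits near the duty cycle (≈ 0.1), far below the *net-input*
level (≈ 1) where winner selection is decided. The set-point integral form
places the threshold in net-input units automatically, just below the
neuron's preferred drive. ACh depletion is modelled by setting the TC
shifting velocity to zero (thresholds frozen); SS homeostasis is
unaffected.

### Synaptic learning

Modifiable synapses follow the presynaptic rule with metaplasticity. For
the TC→SS matrix:

```
Δw = ξ · pre · post · (post − w),     ξ = 0.0019
```

The change vanishes without presynaptic activity, vanishes again exactly at
`post = w` (the LTP threshold, which therefore grows with the weight —
metaplasticity), is depressing for `0 < post < w` and potentiating above.
Crucially it also vanishes at `post = 0`: silent neurons neither gain nor
lose weight, so memories survive disuse and an unspecialized neuron retains
its (random) synaptic profile until it wins something. The fixed point
under sustained co-activity is `w* = post`.

The ancillary recall connections (SS→input) use the linear presynaptic form
`Δv = ξ · pre · (post − v)`. Here the postsynaptic side is the *forced*
sensory neuron, so a zero postsynaptic rate is an explicit teaching signal
("this pixel is absent from the current pattern") and depression at zero
post is what lets a recall row forget a replaced pattern. These virtual
connections are write-only — they never feed back into the dynamics — and
each winner's row converges to the pattern that fires it (readout cosine
similarity > 0.99 after physiological training).

### Normalization and inhibition

While GABA-A signalling is intact, the *entire* SS net input — weighted TC
drive, plus the autapse (fixed weight 0.85), minus basket inhibition — is
divided by the l1-norm of the TC output vector (guarded: a vanishing norm
yields zero drive). Division of the total depolarization is the
biologically meaningful reading of shunting inhibition and is also what
keeps SS net inputs inside [0, ~1.1], the range a threshold clamped to
[0, 1] can actually reach; normalizing only the feedforward term leaves net
inputs the homeostat cannot catch, and perpetual winners become
invulnerable. Removing GABA-A simply bypasses the division.

Each basket cell relays its spiny cell's output (weight 0.98) and inhibits
the other nine spiny cells subtractively; the basket→SS weight defaults to
the same 0.98 (the circuit's two basket constants, 0.98 and 0.5, are given
without an unambiguous direction; both placements are configurable, and the
0.5 constant is retained as the nominal SB→SS conductance while the divisor
gain stays 1.0 because exact scale invariance requires the plain l1-norm).

### Update order within an iteration

TC outputs, weights and shifts follow synchronous semantics (every quantity
computed from the previous iteration's values). The SS layer, however, is
updated *asynchronously within the iteration*, one neuron at a time in
latency order — most-above-threshold first, ties to the lowest index — with
each neuron seeing the basket activity of those already updated. This is
the standard convergence device for discrete-time attractor dynamics: a
fully synchronous spiny layer provably falls into a symmetric
all-fire/all-silent period-2 cycle under strong lateral inhibition, in
which all neurons receive identical histories and can never specialize.
The latency ordering implements "the neuron closest to threshold fires
first" and lets a single leader suppress the pool within one iteration.
A deliberately naive loop implementation of the same semantics serves as
the oracle for the production step in the test suite.

## Stimuli

The canonical bank holds the digits 0–9 plus the letter X on a 5×3 grid.
The glyphs are a package convention designed under two constraints that the
competitive dynamics impose:

* **Every pair of digits differs in at least 3 pixels.** The threshold of a
  winner rides a sawtooth of amplitude ≈ 8υ ≈ 0.14 (it climbs while the
  neuron fires its pattern and decays over the other nine); a rival pattern
  whose normalized drive sits within that ripple of the neuron's own drive
  is transiently invaded, and with classic seven-segment glyphs (several
  pairs at distance 1) one pattern deterministically fails to secure an
  owner.
* **No digit is a near-superset of another.** The normalized drive is a
  weighted mean over the active pixels, so the owner of a subset pattern
  responds almost fully to its superset; the '8' glyph is therefore drawn
  with a pinched waist.

The X glyph (corners plus centre column) is at distance ≥ 2 from every
digit and overlaps each moderately, giving whichever neuron is freed by the
substitution a usable head start; X-versus-8 ownership is resolved by the
homeostatic rate pressure.

## Experiments

Interventions are scheduled as percentages of the life span and fire at
epoch boundaries, before that epoch's presentations. The preset battery
(a1–d1) reproduces the standard table: GABA-A loss at 50 %, ACh loss at
50 %, memantine at 55 %, stimulus halving at 60 %, pattern substitution at
70 % (85 % in d1), pruning from 75 %, GABA-A restoration at 75 % in d1.
Pruning removes `ceil(0.017 × surviving)` of the smallest surviving TC→SS
weights once per 1 % of the life span (the per-iteration reading would
empty the matrix within an epoch); the 1 % cadence follows the synaptic-
density-per-year mapping of a 2,000-epoch life span. Pruned synapses are
masked permanently. The ancillary virtual connections are not pruned (they
are a readout, not anatomy). Each experiment is repeated 20 times; a single
master seed spawns independent streams for the weight initialization and
the substituted-digit draw, so changing one consumer does not shift the
other.

## Observables and the hypermetabolism detector

*Average output* is the mean over the 36 modelled non-sensory neurons
(15 TC + 10 SS + 10 B + 1 SB); *average shift* is the mean over the 25
IP-bearing neurons (TC and SS; basket cells carry no threshold, so the
"not counting sensory neurons" average is taken over the neurons that have
a shift at all). Both are logged at iteration resolution; per-epoch means
are the level curves.

The pathological oscillations live at the iteration time scale — the
population flips between high- and low-output configurations every few
iterations — so per-epoch means are nearly flat while the within-epoch
band is wide. The detector therefore slides a one-epoch window over the
iteration-level average-output trace and marks an epoch oscillatory when
the window's peak-to-peak amplitude reaches 0.2 *and* the window crosses
its own mean at least twice (which excludes one-off level changes such as
the stabilization drop after stimulus reduction with intact GABA-A).
Maximal oscillatory runs of ≥ 5 epochs are reported as intervals;
*hypermetabolism* is declared when a run lasts ≥ 100 epochs. The amplitude
convention was calibrated on the contrast the model is built around:
physiological pattern-to-pattern variation spans ≈ 0.11 within an epoch,
the GABA-A-loss transient reaches ≈ 0.25 for a few tens of epochs, and the
GABA-A-loss-plus-stimulus-reduction regime sustains ≈ 0.28 or more for
hundreds of epochs. The winner-probe (which spiny cell fires for a
pattern) presents the pattern for 8 iterations on a copy of the state with
both learning and threshold adaptation frozen, so measurement never
perturbs the experiment; a pattern has a winner when exactly one spiny
cell's mean output exceeds 0.5.

## What the model does and does not capture

Passing the battery shows that the *mechanisms* — normalization as a
protective factor, homeostatic threshold hunting as the oscillation source,
frozen weights preserving old memories at the cost of new learning —
interact as described. The stimuli are noise-free binary patterns presented
on a fixed schedule; there is no trial-to-trial variability, no spiking,
no conduction delay, and metabolism itself is never modelled (only the
oscillation proxy). Numerical behaviour at the saturated tails of the
logistic (|k(net−s)| > ~37) is exactly 0 or 1 in double precision, which
the tests treat as weak monotonicity. Results are bit-reproducible for a
given seed; the compiled kernel and the pure-Python step agree to 1e-12
and either can run every experiment (the kernel is ~100× faster).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full study sizes: 1,000
epochs for physiological training and 2,000 for each preset, 20 repetitions
per experiment (about 180 simulations in total, roughly a minute of compute
after JIT compilation).
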