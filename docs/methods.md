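# Methods

## Model

A node consists of K independent dendritic terminals.  Terminal i carries
a scaled voltage `V_i` (rest 0, threshold 1) with leak time constant
`T = 20 ms`, a terminal weight `J_i` (initially 1, clamped to
`[1e-6, 10]`), and `N/K` incoming links with static weights `W_m` and
delays `tau_m`.  An arriving pulse increments the voltage by `J_i * W_m`
instantaneously.  A crossing (`V_i >= 1`) emits a spike with probability
`min(1, dt_cross * f_c)`, where `dt_cross` is the time since the
terminal's previous crossing — successful or failed, both reset the clock,
which is the only reading that saturates the stationary terminal rate at
`f_c`.  On a spike the voltage resets to rest; on a response failure it
reverts to its value before the pulses of the crossing step.

Refractoriness is node-wide for 2 ms after a spike: the evoking terminal
does not respond to stimulations (its voltage is unaffected), no terminal
may cross, and sibling voltages keep integrating.  A sibling that sits
above threshold when the refractory period ends undergoes a delayed
crossing at that moment.  Simulation is fixed-step (1 ms for the
feedforward protocols, 0.1 ms otherwise) with the exact per-step leak
factor `exp(-dt/T)`; pulses are binned to their arrival step (delays
rounded to bins), and within a step the order is leak, then all
deliveries, then threshold resolution — highest voltage first, ties to
the lowest terminal index, one attempt per terminal per step.

Adaptation is pair-based: every sub-threshold stimulation on terminal i
combined with every spike from a different terminal of the same node
within 50 ms applies `J_i <- clamp(J_i * (1 + delta) + eta)` with
`delta = A * exp(-|D|/15 ms) * sign(D)`, `D = t_sub - t_spike`.
Post-spike stimulations therefore potentiate, pre-spike ones depress.
Noise `eta` is uniform on `[-0.5, 0.5] * 1e-3`, redrawn per event; the
simplified two-level profile (`+-A` inside the cutoff) is available as
`profile_kind="two_level"`.  Pairs with `D = 0` (same step) carry
`sign(0) = 0` and are skipped, which also keeps the two online pairing
paths symmetric in their noise usage.  In the adaptive-link baseline the
same rule acts on individual `W_m` (single terminal, `J = 1`, lower clamp
at 0, no upper clamp).

Two event-taxonomy rules matter and were settled by validating against
the phenomena the model must produce (see *Interpretation choices*):

* Arrivals during the evoking terminal's 2 ms blindness do not move the
  voltage but **are** sub-threshold stimulations and take part in pairing.
* A failed crossing is logged as a failure, not a stimulation; the pulses
  of a failure step pair with nothing.

## Interpretation choices (failure/refractory micro-semantics)

The verbal model admits several readings of (i) what "previous value"
spans on a failure, (ii) how a sibling's would-be crossing during
refractoriness is handled, and (iii) which arrivals count as
sub-threshold stimulations.  All 24 combinations were implemented (they
remain available as `simulate()` options `failure_reset_to_rest`,
`refractory_mode`, `stims_on_failure`, `blind_stimulations`,
`refractory_failure_stimulations`) and compared against the phenomena the
model is supposed to exhibit.  Two observations fix the default:

* Treating every non-spiking arrival as a stimulation collapses all
  weights to the lower clamp; pairing only rebuild-phase arrivals while
  annulling sibling crossings during refractoriness (forced failures)
  yields a sub-threshold interior equilibrium for the K=2 random-input
  node but lets the recurrent K=3 network degenerate: during the
  synchronized transient only the highest-J terminal of a node can
  discharge per volley, two-thirds of the terminals die, and the network
  settles at ~15 Hz/node instead of `K * f_c` = 45 Hz.
* The default therefore keeps suspended sibling crossings alive through
  the refractory period (delayed crossing at its end) and lets
  blind-window arrivals pair.  The recurrent network then recovers to
  44-45 Hz/node and 15 Hz/terminal, the feedforward taxonomy and
  fractions, the attractor census, the adaptive-link freeze, the
  stationary log-normal and its restoring force, and the collapse at
  vanishing refractory period all hold.  The cost is that the K=2
  random-input equilibrium sits adjacent to the upper weight clamp
  (`W*J` mode ~1.0-1.4) rather than clearly below threshold.

**Known limitation — spike-pair ordering.**  The strong-before-weak
ordering of near-coincident spike pairs (`P_SW > P_WS`) is *not*
reproduced: measured ratios are 0.9-1.1 across long runs, seeds, and all
24 semantic variants.  The reason appears structural: with the crossing
clock reset at every crossing, each terminal's spike emission is a
flat-hazard process at rate `f_c` whenever its voltage dynamics are fast
compared to `1/f_c` (true at these input rates), regardless of its
weight, so consecutive cross-terminal ordering is symmetric up to
`O(f_c * refractory)` corrections.  A spike probability that grows with
the rebuild time would create the ordering but breaks the `f_c`
saturation property.  The corresponding acceptance test asserts the
ordering and fails by design; the restoring force itself is nevertheless
present, carried by the asymmetry in stimulation *counts and timing*
around strong versus weak spikes rather than by pair ordering.

## Networks and stimuli (the synthetic study conditions)

* **Feedforward**: N input units, one output node, one link per input
  (weights U[0.1, 1.1], delays U[1, 150] ms), links delay-sorted into
  consecutive terminal blocks of N/K with the maximal-delay link
  re-assigned to the first terminal (closing the arrival loop).  Drive:
  all inputs simultaneously at 5 Hz; unbounded `f_c`; no adaptation
  noise; A = 0.05.
* **Two-pool**: two pools of equal size, each node wired to `in_degree`
  partners sampled without replacement from the opposite pool; weights
  U[0.1, 0.2]; delays Normal(100 ms, 2 ms) truncated at 0.1 ms;
  delay-sorted consecutive terminal blocks.  `adaptive_link` mode builds
  the single-terminal baseline.
* **Random recurrent**: as two-pool but partners drawn uniformly from all
  other nodes (no self-loops, no repeats).
* **Stimuli**: periodic simultaneous input firing; independent per-input
  Poisson trains; or an initial above-threshold trigger of 40% of the
  nodes plus 0.01 Hz per-node background.  Above-threshold node triggers
  are delivered as a 1.3-threshold pulse to terminal 0 and obey the
  response-failure rule.

What the generator does *not* emulate: inhibition (all weights are
positive), conductance-based membranes, structured or distance-dependent
connectivity, input correlations beyond the initial trigger, and any
feature of recorded biological data.  Passing tests therefore demonstrate
properties of this model class, not of real tissue.

## Protocols and problem sizes

All randomness derives from one seed per run via `numpy.random.SeedSequence`.

* **Oscillation fractions** — 500 random (W, tau) configurations per
  point; each runs 1000 s at 1 ms resolution and is classified on the
  last 600 s of terminal-weight traces sampled stroboscopically at the
  5 Hz stimulation period (a period-one orbit reads as fixed).  The
  horizon matters: fixed-point convergence can take hundreds of seconds,
  and the fractions stop drifting near this horizon.  Classifier:
  fixed if every terminal's coefficient of variation is below `1e-3`;
  otherwise the dominant period of the spectral product decides fast
  versus slow at a 2 s boundary, and slow additionally requires a
  relative amplitude range above 0.5 of the global maximum (the
  plateaus-at-the-clamps phenotype).  Dominant periods longer than a
  quarter of the window are flagged *indeterminate*: within a finite
  window an unfinished approach to a fixed point is operationally
  indistinguishable from a very long period, so such labels are counted
  as oscillating for the fractions (matching the finite-horizon
  character of the published estimate) but are not treated as bounded
  observations of slow oscillation in the K=2 taxonomy check.
* **Attractor census** — K=3, three inputs per terminal; per initial
  condition a 300 s run at 5 Hz with per-link firing/non-firing counts
  over the final 100 s; two runs share an attractor when every link's
  firing count differs by less than 2% (links with fewer than 10 firing
  events are compared on non-firing counts); greedy first-seen
  representative clustering.  The test suite runs the scaled surrogate
  (6 delay sets x 200 initial conditions, growth and consistency); the
  full census toward saturation is hours of compute and is exposed via
  `dendrosim attractor-census --set n_initial_conditions=...`.
* **Recurrent steady state** — 200 nodes (scaled from 1000), K=3,
  in-degree 60, `f_c` = 15 Hz, A = 0.05, dt = 0.1 ms, 240 s with rates
  measured over 220-240 s: the scaled network needs ~200 s for the
  trigger-induced transient (during which a minority of terminals is
  driven to the lower clamp and must diffuse back) to clear.
* **Random-input node** — K=2, 60 links per terminal (weights
  U[0.1, 0.2], zero delay; inputs are Poisson so delays are pure time
  shifts), every input Poisson at `K * f_c` = 30 Hz, A = 0.1, 2500 s with
  a 200 s transient excluded.  Effective weights are sampled every 50 ms;
  adaptation events are logged post-transient for the force estimate.
* **Two-pool comparison** — 200 nodes; adaptive-node mode for 50 s,
  adaptive-link baseline for 350 s; mobility measured as per-link max/min
  of the effective weight over the final 2 s (capped at 60 in link mode,
  where a link below 0.01 — an order of magnitude under the smallest
  initial weight — counts as vanished).
* **Refractory sweep** — the random-input configuration re-run per
  refractory period; at 0 ms every effective weight ends above threshold.

## Statistical choices

* **Log-normal diagnostics**: a normal distribution is fitted to
  `ln(W*J)` by maximum likelihood; the KS statistic is computed on the
  pooled post-transient samples but its p-value uses the number of
  *links* (120) as effective sample size — temporally pooled samples of
  the same links are strongly autocorrelated, and the pooled count would
  fabricate significance.  Histograms use 100 bins in log10 space.
* **Strong/weak construction**: weak = percentile band [1%, 25%],
  strong = [75%, 99%] of the pooled effective weights; each holds 24% of
  the distribution up to ties (weights pinned at the clamp tie exactly).
* **Pair ordering**: consecutive spikes of one node from distinct
  terminals within 5 ms; a terminal is strong/weak at pair time by its
  current mean effective weight against the global bands; the null is a
  within-pair label shuffle.
* **Restoring force**: adaptation events are binned by `W*J` at the
  event (bin width 0.05); each bin reports `mean(J+ - J) / <W*J>` with
  the per-bin standard deviation; empty bins are absent.  The sign-change
  locator requires at least 100 events per bin.
* **Scale invariance**: voltages are stored relative to rest in
  threshold-normalized units; builders accept physical `v_st`/`v_th` and
  scale weights by the span, so an affine rescaling (e.g. rest -70 mV,
  threshold -54 mV) reproduces spike times exactly for power-of-two
  spans.

## Numerical notes

* Delays of recurrent (node-sourced) links are floored at one step so a
  spike never feeds back into its own emission step.
* Pairing buffers keep the last 50 ms of stimulations per terminal (512
  slots) and spikes per node (64 slots); capacities exceed the worst
  sustained rates of the standard protocols by a safe margin.
* The engine refuses to silently drop data: ring-buffer or log overflow
  aborts the run with an error.
* Degenerate inputs: zero-rate stimuli produce empty schedules; an empty
  network simulates to silence; a refractory period of 0 disables all
  suppression; `f_c = inf` disables response failures.
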