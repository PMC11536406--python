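# Methods

## The model

`alifp` simulates a single electrically stimulated auditory nerve fiber as
a *nonspiking* adaptive-threshold model: instead of drawing noisy
thresholds and emitting stochastic spike times, every computation is done
directly on the distributions, so one deterministic run yields the total
firing probability and the full spike-time distribution per pulse.

**Membrane.** The passive potential obeys a linear leaky integrator,
`tau dV/dt = -R I(t) - V + V_rest`, with cathodic (negative) current
depolarizing. Because the stimulus is piecewise-constant (rectangular
biphasic pulses), the ODE is solved in closed form per segment; values at
arbitrary times are exact and the 1 µs grid is used only for reporting and
probability evaluation. The potential is deterministic, shared by all
threshold paths, and never reset by a spike.

**Threshold.** The firing threshold is a Gaussian `N(mu_theta(t),
sigma_theta(t))` with resting values `m_theta = 10 mV`, `s_theta =
0.43 mV`. History modifies both multiplicatively:

* *facilitation / accommodation* after a pulse that did not fire:
  `F(t) = (1 - e^{-f4 (t+f1)}) (1 + f3 e^{-f4 (t+f2)})`, anchored at the
  end of the leading phase. F dips below 1 for ~0.5 ms (facilitation),
  rises above 1 for a few ms (accommodation), and converges to 1. The
  accumulated F-product is floored at `f5 = 0.5`.
* *refractoriness* after a spike: infinite during the absolute period
  `t_ARP = 0.37 ms`, then
  `[(1 - e^{-(t+t_ARP)/(q tau_RRP)})(1 - p e^{-(t+t_ARP)/tau_RRP})]^{-1}`,
  anchored at the mean threshold-crossing time `mu_ct`.
* *adaptation* after a spike: `A(t) = 1 + c_a e^{-t/tau_a}` with
  `c_a = 0.015`, `tau_a = 0.27 s`; the accumulated A-product is capped at
  `a_max = 1.7`.

Factors compose commutatively on the baseline; each kind's bound applies
to its own sub-product before the kinds are multiplied, so the bounds stay
independent of one another. Finally `sigma` is capped at `b * mu`
(`b = 1/3`), which keeps the firing probability at zero stimulus amplitude
at the Phi(-3) ≈ 0.1% level even for pathological parameterizations. With
the default parameters `sigma/mu = 0.043` everywhere (all modifiers scale
mean and s.d. identically), so the cap is inactive and the relative spread
of rate-level curves is constant — a deliberate property of the model.

**Spike cancellation.** A charge-balanced second phase can abort an
action potential whose initiation period (`phi = 20.5 µs`) extends past
the excitatory phase. For rectangular phases this is equivalent to a
threshold offset: the minimum lead-in `phi_n_min = (phi - d_IPG) /
(1 + a_n/a_p)` fixes a crossing deadline `t_cancel = t_start + d_lead -
phi_n_min`, and since V rises strictly until the end of the cathodic
phase, `o_cancel = V_max - V(t_cancel) >= 0` raises the effective
threshold. Monophasic pulses, zero-amplitude phases and gaps longer than
`phi` give zero offset. This mechanism is the reason the simulator is
restricted to rectangular biphasic pulses.

**Firing probability and spike time.** Per pulse and per path,
`Ps = max_t Phi((V(t) - mu_theta(t) - o_cancel) / sigma_theta(t))` over
the leading phase, evaluated on the 1 µs grid augmented with the analytic
time of V_max so grid coarseness never clips the maximum. The crossing
curve `g(t) = Phi((V - mu_theta)/sigma_theta)` (offset excluded) is fitted
with `a·Phi((t - mu_ct)/sigma_ct)`, `a` pinned to the terminal plateau;
a probit-scale linear regression seeds a Levenberg–Marquardt refinement,
with a quantile fallback. Latency mean and jitter are logistic in the
headroom `V_max - (mu_theta(mu_ct) + o_cancel)` — they keep shrinking even
after Ps saturates at 1 — and the spike time is the sum of the two
independent Gaussians: `mu_st = mu_ct + mu_L`,
`sigma_st^2 = sigma_ct^2 + sigma_L^2`.

**Path branching.** After each pulse every path splits into a spike child
(weight `w·Ps_k`, gaining refractory + adaptation events at its own
`mu_ct`) and a no-spike child (weight `w·(1-Ps_k)`, gaining a fac_acc
event at the end of the leading phase). The pulse's total probability is
`sum_k w_k Ps_k` (law of total probability), which keeps totals in [0,1];
the per-pulse spike-time mixture weights are `w_k Ps_k` renormalized, and
are exported *before* pruning. Paths with identical event histories
(anchors quantized to the grid) merge by weight addition; then the
lowest-weight components are dropped until at most `K_max = 20` remain
(older survives ties) and weights are rescaled.

## Numerical choices

* **Grid**: 1 µs default everywhere (probability evaluation, crossing
  fit, trace sampling, anchor quantization); configurable.
* **Branching floor**: paths with conditional probability <= 1e-12 are
  not given a spike child — a zero-amplitude train therefore keeps exactly
  one path. Crossing curves peaking below 1e-9 contribute no spike-time
  mass.
* **Event horizon**: modifier events whose factor has recovered to within
  ~1e-7 of unity are dropped (fac_acc after 30 ms, refractory after
  60 ms, adaptation after 6 s). This bounds the per-pulse cost of long
  trains, is far below every tolerance used here, and lets equivalent
  paths merge.
* **Degenerate crossing fits** (probability jumps within one grid step):
  the quantile method stands in; when even that is unavailable but the
  path can fire, the time of the window maximum substitutes for `mu_ct`
  (logged).
* **I50 search**: bisection on the amplitude magnitude (probability is
  monotone in it for a fixed shape), upper bracket found by doubling from
  twice the monophasic strength-duration estimate; tolerance 1e-6 in
  probability. A fully refractory state reports a bracket failure rather
  than a spurious root.

## The Monte-Carlo oracle

The sampler draws thresholds and latencies from the same Gaussians the
analytic engine manipulates, shares the event implementation, and follows
one realized history per run. Its default *pointwise* semantics draws the
threshold once per pulse at the probability-maximizing time — exactly the
pointwise-max quantity the analytic model defines — so the empirical rates
are an unbiased check of the full pipeline. A *first-passage* mode
(independent redraw at every grid step, spike on any crossing) is also
provided; it is a strictly larger probability and is not what the analytic
model computes. Equivalence tests compare trains on the unpruned branching
tree, because the sampler follows real outcomes and cannot prune; the
K_max=20 pruning is a separately bounded approximation (the component-cap
check). Runs sharing a history are processed together, so cost scales with
the number of distinct histories, not with the number of runs.

## Protocol fixtures

The fixture registry reproduces the structure of the characterization
protocols: strength-duration (25–200 µs phases), mono/biphasic rate-level
(100 µs), refractory recovery and facilitation masker-probe pairs (100 µs
monophasic), accumulated facilitation (4 and 40 maskers at 1 ms spacing),
adaptation trains (40 µs biphasic, 250/1,000/5,000 pps at 1.4 and 3.1/4.0
dB re I50), masker-probe recovery (200 ms masker at 250 or 5,000 pps plus
a 250 ms 100 pps probe, 40 µs phases, 30 µs gap, masker at −2.7 dB and
probe at −1.4 dB re the single-pulse I50), vector strength (40 µs phases,
gaps of 0 and 30 µs, rates 100–5,000 pps at the 90%-probability
amplitude), and amplitude modulation (5,000 pps, m = 0.1, f_m = 100 Hz).
Where a protocol's train length or masker level is not specified, a value
was fixed once: 300 ms adaptation trains, 50 ms vector-strength trains,
100 ms AM trains, 0.8 I50 subthreshold maskers, 2 I50 refractory maskers.
Amplitude modulation samples the envelope once per pulse at its onset
(phase durations are ≪ the modulation period).

These fixtures emulate idealized stimulation of a single fiber with the
fitted parameter set. They contain no electrode-to-neuron interface, no
across-fiber parameter spread, and no anodic excitation; passing tests
demonstrate internal consistency of the model and its published reference
values, not agreement with any particular animal recording.

## Problem sizes

The verification suite uses single pulses, pulse pairs, 10-pulse trains
(Monte-Carlo comparisons at n = 20,000 runs) and 100-pulse trains (the
component-cap check); fixture smoke tests simulate the first 15 pulses of
each protocol train. Full-length protocol runs (for example the 200 ms,
5,000 pps masker) are supported through the same `simulate` entry point
and scale linearly in pulse count times mixture size.

## Known limitations

* Only rectangular biphasic (or monophasic-encoded) pulses; no
  triphasic or non-rectangular shapes.
* Only cathodic leading phases excite; anodic excitation via a second
  threshold is not implemented.
* Spike-time components are Gaussian by construction; skewed empirical
  distributions are not representable.
* Relative-spread changes during refractoriness are outside the model:
  mean and s.d. carry identical factors, so the spread is constant.
* The jitter law depends on the membrane-potential headroom, which is
  known to overestimate jitter at low per-pulse probabilities in
  high-rate trains.
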