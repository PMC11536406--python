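"""Monte-Carlo spiking sampler used as a brute-force verification twin.

The analytic engine never draws a random number: it propagates the
threshold *distribution*.  This sampler instead draws noisy thresholds and
latencies from the very same Gaussians and follows one realized
spike/no-spike history per run, applying the identical modifier-event
rules (shared with :mod:`alifp.threshold_state` / :mod:`alifp.path_engine`).
Empirical firing rates, outcome frequencies and spike-time histograms from
many runs must then agree with the analytic probabilities, path weights
and spike-time mixtures within sampling error.

Two stochastic semantics are available:

* ``pointwise`` (default) — the threshold is drawn once per pulse, at the
  time maximizing the instantaneous firing probability.  This samples
  exactly the pointwise-max quantity the analytic model defines, so the
  comparison is an unbiased check of the whole pipeline (membrane,
  modifiers, cancellation, branching).
* ``first_passage`` — the threshold is redrawn independently at every grid
  step and a spike occurs on any crossing.  This is a genuinely different
  (larger) probability, provided for comparison; it is *not* what the
  analytic model computes.

Runs sharing a history are processed together, so the per-history analytic
work is done once regardless of the number of runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .membrane import MembranePotential
from .params import ModelParams
from .path_engine import _event_key
from .pulse_response import cancellation_offset, component_response
from .stimulus import PulseTrain
from .threshold_state import (
    ADAPTATION,
    FAC_ACC,
    REFRACTORY,
    ModifierEvent,
    ThresholdComponent,
    compress_events,
    evaluate,
)

__all__ = ["SampledRun", "sample_run", "sample_runs", "empirical_summary"]

Mode = Literal["pointwise", "first_passage"]


@dataclass(frozen=True)
class SampledRun:
    """One realized history: per-pulse outcomes and the drawn spike times."""

    seed: int
    spike_times: tuple[tuple[int, float], ...]
    outcome_path: tuple[bool, ...]


def sample_runs(
    train: PulseTrain,
    params: ModelParams,
    n: int,
    seed: int,
    mode: Mode = "pointwise",
) -> list[SampledRun]:
    """Draw ``n`` independent runs of the stochastic twin of the model.

    All runs share one root generator seeded with ``seed``; a fixed seed
    reproduces the full population bit-exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("pointwise", "first_passage"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    potential = MembranePotential.from_train(train, params.membrane)
    thr = params.threshold
    n_pulses = len(train.pulses)

    outcomes = np.zeros((n, n_pulses), dtype=bool)
    spike_time = np.full((n, n_pulses), np.nan)

    # nodes: quantized-history key -> (representative events, run indices)
    nodes: dict[tuple, tuple[tuple[ModifierEvent, ...], np.ndarray]] = {
        (): ((), np.arange(n))
    }
    for i, pulse in enumerate(train.pulses):
        canc = cancellation_offset(pulse, potential, params.phi)
        t0, t1 = pulse.t_start, pulse.t_lead_end
        grid = np.unique(
            np.concatenate(
                [
                    t0 + params.grid_step * np.arange(int((t1 - t0) / params.grid_step) + 1),
                    [t1, canc.t_of_max],
                ]
            )
        )
        grid = grid[(grid >= t0) & (grid <= t1)]
        v = np.asarray(potential(grid))

        children: dict[tuple, tuple[tuple[ModifierEvent, ...], list[np.ndarray]]] = {}

        def add_child(events: tuple[ModifierEvent, ...], idx: np.ndarray) -> None:
            if idx.size == 0:
                return
            events = compress_events(events, pulse.t_end)
            key = _event_key(events, params.grid_step)
            if key in children:
                children[key][1].append(idx)
            else:
                children[key] = (events, [idx])

        for events, idx in nodes.values():
            comp = ThresholdComponent(1.0, events)
            mu, sigma = evaluate(comp, grid, thr)
            finite = np.isfinite(mu)
            if not finite.any():
                add_child(events + (ModifierEvent(FAC_ACC, t1),), idx)
                continue
            if mode == "pointwise":
                score = np.where(finite, (v - mu - canc.o_cancel) / sigma, -np.inf)
                j = int(np.argmax(score))
                theta = rng.normal(mu[j], sigma[j], size=idx.size)
                fired = v[j] >= theta + canc.o_cancel
            else:
                cols = np.flatnonzero(finite)
                theta = rng.normal(mu[cols], sigma[cols], size=(idx.size, cols.size))
                fired = np.any(v[cols][None, :] >= theta + canc.o_cancel, axis=1)

            idx_spike = idx[fired]
            idx_quiet = idx[~fired]
            if idx_spike.size:
                pr = component_response(
                    pulse, potential, comp, thr, params.latency, canc,
                    grid_step=params.grid_step,
                )
                if pr.spike_time is not None:
                    st = pr.spike_time
                    ct = rng.normal(st.mu_ct, st.sigma_ct, size=idx_spike.size)
                    lat = rng.normal(st.mu_l, st.sigma_l, size=idx_spike.size)
                    anchor = st.mu_ct
                else:  # vanishing analytic probability but a draw fired anyway
                    ct = np.full(idx_spike.size, canc.t_of_max)
                    lat = np.zeros(idx_spike.size)
                    anchor = canc.t_of_max
                outcomes[idx_spike, i] = True
                spike_time[idx_spike, i] = ct + lat
                add_child(
                    events
                    + (
                        ModifierEvent(REFRACTORY, anchor),
                        ModifierEvent(ADAPTATION, anchor),
                    ),
                    idx_spike,
                )
            add_child(events + (ModifierEvent(FAC_ACC, t1),), idx_quiet)

        nodes = {
            key: (events, np.concatenate(parts))
            for key, (events, parts) in children.items()
        }

    runs: list[SampledRun] = []
    for r in range(n):
        spikes = tuple(
            (int(i), float(spike_time[r, i]))
            for i in np.flatnonzero(outcomes[r])
        )
        runs.append(
            SampledRun(seed=seed, spike_times=spikes, outcome_path=tuple(outcomes[r]))
        )
    return runs


def sample_run(
    train: PulseTrain, params: ModelParams, seed: int, mode: Mode = "pointwise"
) -> SampledRun:
    """Draw a single run (deterministic for a fixed seed)."""
    return sample_runs(train, params, n=1, seed=seed, mode=mode)[0]


def empirical_summary(runs: list[SampledRun], bin_width: float = 1e-6) -> dict:
    """Aggregate a run population.

    Returns per-pulse empirical firing rates, the pooled spike times, a
    histogram of them at ``bin_width`` resolution, and the frequency of
    each realized outcome path (for multinomial checks against the
    analytic path weights).
    """
    if not runs:
        raise ValueError("need at least one run")
    n_pulses = len(runs[0].outcome_path)
    counts = np.zeros(n_pulses)
    all_times: list[float] = []
    path_freq: dict[tuple[bool, ...], int] = {}
    for run in runs:
        for i, fired in enumerate(run.outcome_path):
            counts[i] += fired
        all_times.extend(t for _, t in run.spike_times)
        path_freq[run.outcome_path] = path_freq.get(run.outcome_path, 0) + 1
    times = np.asarray(all_times)
    if times.size:
        lo = np.floor(times.min() / bin_width) * bin_width
        hi = np.ceil(times.max() / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        hist, edges = np.histogram(times, bins=edges)
    else:
        hist, edges = np.zeros(0, dtype=int), np.zeros(1)
    return {
        "n_runs": len(runs),
        "per_pulse_rate": counts / len(runs),
        "spike_times": times,
        "histogram": (hist, edges),
        "path_frequencies": path_freq,
    }
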