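"""Sequential pulse-train simulation over the branching threshold mixture.

After each pulse every threshold path splits in two: a *spike* child
(weight ``w * Ps_k``) inheriting refractory and adaptation events anchored
at that path's mean crossing time, and a *no-spike* child (weight
``w * (1 - Ps_k)``) inheriting a facilitation/accommodation event anchored
at the end of the leading phase.  The total firing probability of a pulse
is the law-of-total-probability sum ``sum_k w_k * Ps_k``, which keeps
every per-pulse total inside [0, 1].

To bound the exponential growth, paths with identical modifier histories
(anchors quantized to the evaluation grid) are merged, and the mixture is
then pruned to the ``k_max`` heaviest components (older components survive
ties), with weights rescaled to one.  Spike-time mixtures are exported
*before* pruning so a pulse's reported distribution is unpruned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .membrane import DEFAULT_GRID_STEP, MembranePotential
from .params import ModelParams
from .pulse_response import (
    PS_FLOOR,
    PathResponse,
    PulseResponse,
    SpikeTimeComponent,
    cancellation_offset,
    component_response,
)
from .stimulus import PulseTrain
from .threshold_state import (
    ADAPTATION,
    FAC_ACC,
    REFRACTORY,
    ModifierEvent,
    ThresholdComponent,
    ThresholdMixture,
    compress_events,
)

__all__ = [
    "ProbabilityTrace",
    "SimulationResult",
    "split_paths",
    "prune",
    "simulate",
    "mean_spike_rate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProbabilityTrace:
    """Instantaneous firing probability density over time (1/s).

    The density is the per-pulse spike-time Gaussian mixture scaled by that
    pulse's total firing probability, so the integral over one pulse's
    support equals its total probability.
    """

    times: np.ndarray
    density: np.ndarray
    grid_step: float = DEFAULT_GRID_STEP


@dataclass(frozen=True)
class SimulationResult:
    """Per-pulse responses, the probability trace, and the final mixture.

    ``path_counts`` and ``weight_sums`` record the mixture size and total
    weight after each pulse (post-prune), for diagnostics and invariants.
    """

    responses: tuple[PulseResponse, ...]
    trace: ProbabilityTrace
    final_state: ThresholdMixture
    path_counts: tuple[int, ...]
    weight_sums: tuple[float, ...]


def split_paths(
    mixture: ThresholdMixture,
    per_path_ps: list[float],
    spike_anchors: list[float | None],
    fac_anchor: float,
) -> ThresholdMixture:
    """Duplicate each path into spike / no-spike descendants.

    ``per_path_ps`` and ``spike_anchors`` are aligned with the mixture's
    components; a ``None`` anchor (or a probability at the branching floor)
    suppresses the spike child.  The spike child gains a refractory and an
    adaptation event at the path's mean crossing time; the no-spike child a
    fac_acc event at ``fac_anchor`` (end of the leading phase).  The result
    is normalized.
    """
    if len(per_path_ps) != len(mixture.components) or len(spike_anchors) != len(
        mixture.components
    ):
        raise ValueError("per-path lists must align with the mixture components")
    children: list[ThresholdComponent] = []
    for comp, ps, anchor in zip(mixture.components, per_path_ps, spike_anchors):
        if not 0.0 <= ps <= 1.0:
            raise ValueError(f"conditional probability out of range: {ps}")
        if ps > PS_FLOOR and anchor is not None:
            spike_events = comp.events + (
                ModifierEvent(REFRACTORY, anchor),
                ModifierEvent(ADAPTATION, anchor),
            )
            children.append(ThresholdComponent(weight=comp.weight * ps, events=spike_events))
            w_nospike = comp.weight * (1.0 - ps)
        else:
            w_nospike = comp.weight
        if w_nospike > 0.0:
            children.append(
                ThresholdComponent(
                    weight=w_nospike,
                    events=comp.events + (ModifierEvent(FAC_ACC, fac_anchor),),
                )
            )
    return ThresholdMixture(components=tuple(children), k_max=mixture.k_max).normalized()


def _event_key(events: tuple[ModifierEvent, ...], grid_step: float) -> tuple:
    """Merge key: the event multiset with anchors quantized to the grid."""
    return tuple(sorted((e.kind, round(e.anchor / grid_step)) for e in events))


def prune(mixture: ThresholdMixture, grid_step: float = DEFAULT_GRID_STEP) -> ThresholdMixture:
    """Merge identical paths, cap the count at ``k_max``, renormalize.

    Components whose (mean, s.d.) trajectories coincide — operationally,
    identical event lists after quantizing anchors to the grid — are merged
    by weight addition.  Then the lowest-weight components are removed
    until at most ``k_max`` remain (on ties the older, i.e. earlier-listed,
    component survives) and the rest are rescaled to sum to one.
    """
    merged: dict[tuple, int] = {}
    comps: list[ThresholdComponent] = []
    for comp in mixture.components:
        if comp.weight == 0.0:
            continue
        key = _event_key(comp.events, grid_step)
        if key in merged:
            i = merged[key]
            comps[i] = ThresholdComponent(
                weight=comps[i].weight + comp.weight, events=comps[i].events
            )
        else:
            merged[key] = len(comps)
            comps.append(comp)
    if not comps:  # all mass vanished (cannot happen for valid inputs)
        raise ValueError("pruning removed all components")
    if len(comps) > mixture.k_max:
        # stable sort: equal weights keep list (age) order, so older survive
        order = sorted(range(len(comps)), key=lambda i: -comps[i].weight)
        keep = sorted(order[: mixture.k_max])
        comps = [comps[i] for i in keep]
    total = sum(c.weight for c in comps)
    comps = [ThresholdComponent(weight=c.weight / total, events=c.events) for c in comps]
    return ThresholdMixture(components=tuple(comps), k_max=mixture.k_max)


def _build_trace(
    responses: tuple[PulseResponse, ...], grid_step: float, t_end: float
) -> ProbabilityTrace:
    times = np.arange(0.0, t_end + 0.5 * grid_step, grid_step)
    density = np.zeros_like(times)
    for resp in responses:
        if resp.p_s_total <= 0.0:
            continue
        for comp in resp.spike_time_mixture:
            scale = resp.p_s_total * comp.weight
            if comp.sigma_st <= 0.0:
                # degenerate component: all mass in one grid cell
                idx = int(np.clip(round(comp.mu_st / grid_step), 0, len(times) - 1))
                density[idx] += scale / grid_step
                continue
            lo = np.searchsorted(times, comp.mu_st - 8.0 * comp.sigma_st)
            hi = np.searchsorted(times, comp.mu_st + 8.0 * comp.sigma_st)
            tt = times[lo:hi]
            density[lo:hi] += (
                scale
                / (comp.sigma_st * np.sqrt(2.0 * np.pi))
                * np.exp(-0.5 * ((tt - comp.mu_st) / comp.sigma_st) ** 2)
            )
    return ProbabilityTrace(times=times, density=density, grid_step=grid_step)


def simulate(train: PulseTrain, params: ModelParams) -> SimulationResult:
    """Run the full model over a pulse train.

    Per pulse: evaluate every threshold path (probability, crossing fit,
    latency), sum the per-path probabilities into the total, export the
    spike-time mixture, then split, merge and prune the threshold mixture.
    The probability trace covers the stimulus plus a tail for late spikes.
    """
    for p in train.pulses:
        if p.a_lead > 0:
            raise ValueError("every pulse must have a cathodic (non-positive) leading phase")
    potential = MembranePotential.from_train(train, params.membrane)
    mixture = ThresholdMixture.resting(params.k_max)
    grid_step = params.grid_step

    responses: list[PulseResponse] = []
    path_counts: list[int] = []
    weight_sums: list[float] = []
    t_tail = 0.0
    for i, pulse in enumerate(train.pulses):
        canc = cancellation_offset(pulse, potential, params.phi)
        per_path: list[PathResponse] = []
        for k, comp in enumerate(mixture.components):
            pr = component_response(
                pulse, potential, comp, params.threshold, params.latency, canc,
                path_index=k, grid_step=grid_step,
            )
            per_path.append(pr)
        weights = mixture.weights
        p_total = float(np.clip(sum(w * pr.p_cond for w, pr in zip(weights, per_path)), 0.0, 1.0))
        # joint (path x spike) mass becomes the spike-time component weight;
        # PulseResponse.spike_time_mixture renormalizes them to sum to one
        weighted = tuple(
            replace(
                pr,
                spike_time=(
                    None
                    if pr.spike_time is None
                    else replace(pr.spike_time, weight=float(w * pr.p_cond))
                ),
            )
            for w, pr in zip(weights, per_path)
        )
        resp = PulseResponse(
            pulse_index=i,
            t_start=pulse.t_start,
            p_s_total=p_total,
            per_path=weighted,
            o_cancel=canc.o_cancel,
            v_max=canc.v_max,
        )
        responses.append(resp)
        for comp in resp.spike_time_mixture:
            t_tail = max(t_tail, comp.mu_st + 8.0 * comp.sigma_st)

        mixture = split_paths(
            mixture,
            [pr.p_cond for pr in per_path],
            [pr.mu_ct for pr in per_path],
            fac_anchor=pulse.t_lead_end,
        )
        mixture = prune(mixture, grid_step)
        mixture = ThresholdMixture(
            components=tuple(
                ThresholdComponent(weight=c.weight, events=compress_events(c.events, pulse.t_end))
                for c in mixture.components
            ),
            k_max=mixture.k_max,
        )
        mixture = prune(mixture, grid_step)  # compression may expose new merges
        path_counts.append(len(mixture.components))
        weight_sums.append(float(mixture.weights.sum()))
        log.debug(
            "pulse %d: Ps=%.6g, paths=%d", i, p_total, len(mixture.components)
        )

    t_end = max(train.duration, t_tail) + 10 * grid_step
    trace = _build_trace(tuple(responses), grid_step, t_end)
    return SimulationResult(
        responses=tuple(responses),
        trace=trace,
        final_state=mixture,
        path_counts=tuple(path_counts),
        weight_sums=tuple(weight_sums),
    )


def mean_spike_rate(result: SimulationResult, window: tuple[float, float]) -> float:
    """Average spike rate over a window: summed per-pulse firing
    probabilities of the pulses whose (weighted) mean spike time falls
    inside, divided by the window length."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("empty window: need t1 > t0")
    total = 0.0
    for resp in result.responses:
        if resp.p_s_total <= 0.0:
            continue
        comps = resp.spike_time_mixture
        if comps:
            mu = sum(c.weight * c.mu_st for c in comps)
        else:
            mu = resp.t_start
        if t0 <= mu < t1:
            total += resp.p_s_total
    return total / (t1 - t0)
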