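"""Derived response measures: I50, rate-level curves, relative spread,
vector strength, and masker-probe recovery.

These are the summary statistics used to characterize electrically
stimulated fibers: ``I50`` is the amplitude evoking a spike with
probability 0.5, the *relative spread* is the s.d. of the cumulative-
Gaussian rate-level fit divided by I50, and *vector strength* quantifies
phase locking of the spike-time distribution to a stimulus period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .membrane import MembranePotential
from .params import ModelParams
from .path_engine import SimulationResult, mean_spike_rate, simulate
from .pulse_response import cancellation_offset, fit_cumulative_gaussian, firing_probability
from .stimulus import BiphasicPulse, PulseTrain, db_re_ref
from .threshold_state import ThresholdMixture

__all__ = [
    "RateLevelPoint",
    "single_pulse_probability",
    "find_i50",
    "rate_level_curve",
    "relative_spread",
    "vector_strength",
    "probe_recovery_ratio",
]


@dataclass(frozen=True)
class RateLevelPoint:
    """One point of a rate-level function: amplitude magnitude (A), level in
    dB re an optional reference, and the response (probability or rate)."""

    amplitude: float
    value: float
    level_db: float | None = None


def single_pulse_probability(
    pulse: BiphasicPulse,
    params: ModelParams,
    state: ThresholdMixture | None = None,
) -> float:
    """Total firing probability of one pulse given a threshold state.

    The default state is the resting fiber (a single unit-weight path).
    """
    if state is None:
        state = ThresholdMixture.resting(params.k_max)
    train = PulseTrain(pulses=(pulse,), duration=pulse.t_end)
    potential = MembranePotential.from_train(train, params.membrane)
    canc = cancellation_offset(pulse, potential, params.phi)
    window = (pulse.t_start, pulse.t_lead_end)
    total = 0.0
    for comp in state.components:
        total += comp.weight * firing_probability(
            potential, comp, params.threshold, canc.o_cancel, window, params.grid_step
        )
    return float(np.clip(total, 0.0, 1.0))


def find_i50(
    pulse: BiphasicPulse,
    params: ModelParams,
    state: ThresholdMixture | None = None,
    tolerance: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Amplitude magnitude at which the pulse fires with probability 0.5.

    Bisection on the leading-phase amplitude magnitude (both phases scale
    together, preserving the template's amplitude ratio); the firing
    probability is monotone in the magnitude for a fixed shape, so the
    bracket is guaranteed once an upper bound with p >= 0.5 is found.
    """
    if pulse.a_lead >= 0:
        raise ValueError("pulse template must have a cathodic (negative) leading phase")

    base = abs(pulse.a_lead)

    def ps(magnitude: float) -> float:
        return single_pulse_probability(pulse.scaled(magnitude / base), params, state)

    # initial guess: monophasic strength-duration scale for this phase duration
    tau = params.membrane.tau
    a_hi = 2.0 * params.threshold.m_theta / (
        abs(params.membrane.resistance) * (1.0 - math.exp(-pulse.d_lead / tau))
    )
    for _ in range(60):
        if ps(a_hi) >= 0.5:
            break
        a_hi *= 2.0
    else:
        raise ValueError(
            "could not bracket I50: firing probability stays below 0.5 "
            "(is the fiber refractory at this time?)"
        )
    a_lo = 0.0
    for _ in range(max_iter):
        mid = 0.5 * (a_lo + a_hi)
        p = ps(mid)
        if abs(p - 0.5) < tolerance:
            return mid
        if p < 0.5:
            a_lo = mid
        else:
            a_hi = mid
    return 0.5 * (a_lo + a_hi)


def rate_level_curve(
    amplitudes: Sequence[float],
    params: ModelParams,
    pulse: BiphasicPulse | None = None,
    train_builder: Callable[[float], PulseTrain] | None = None,
    window: tuple[float, float] | None = None,
    reference: float | None = None,
) -> list[RateLevelPoint]:
    """Response versus amplitude magnitude.

    In single-pulse mode (``pulse`` given) the response is the firing
    probability; in train mode (``train_builder`` mapping magnitude to a
    train, with an analysis ``window``) it is the mean spike rate.  Levels
    in dB re ``reference`` are attached when a reference is supplied.
    """
    if (pulse is None) == (train_builder is None):
        raise ValueError("provide exactly one of 'pulse' or 'train_builder'")
    points: list[RateLevelPoint] = []
    for a in amplitudes:
        if a < 0:
            raise ValueError("amplitudes are magnitudes; must be >= 0")
        if pulse is not None:
            value = single_pulse_probability(pulse.scaled(a / abs(pulse.a_lead)), params)
        else:
            if window is None:
                raise ValueError("train mode needs an analysis window")
            value = mean_spike_rate(simulate(train_builder(a), params), window)
        level = db_re_ref(a, reference) if (reference is not None and a > 0) else None
        points.append(RateLevelPoint(amplitude=a, value=value, level_db=level))
    return points


def relative_spread(curve: Sequence[RateLevelPoint]) -> float:
    """Relative spread of a single-pulse rate-level curve.

    Fits a cumulative Gaussian Phi((a - a50)/s) to probability-vs-amplitude
    and returns s/a50.  The curve must span probabilities 0.05 to 0.95.
    """
    amps = np.array([p.amplitude for p in curve])
    ps = np.array([p.value for p in curve])
    order = np.argsort(amps)
    amps, ps = amps[order], ps[order]
    if ps.min() > 0.05 or ps.max() < 0.95:
        raise ValueError(
            "rate-level curve must span firing probabilities [0.05, 0.95] "
            f"(got [{ps.min():.3g}, {ps.max():.3g}])"
        )
    a50, s = fit_cumulative_gaussian(amps, ps, plateau=1.0)
    return float(s / a50)


def vector_strength(times: np.ndarray, p: np.ndarray, period: float) -> float:
    """Phase locking of a sampled spike-time distribution to ``period``.

    The resultant length of the probability-weighted phasors: 1 when all
    mass sits at one phase, 0 for mass uniform over the period.
    """
    times = np.asarray(times, dtype=float)
    p = np.asarray(p, dtype=float)
    if times.shape != p.shape:
        raise ValueError("times and probabilities must have matching shapes")
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if not period > 0:
        raise ValueError("period must be positive")
    total = p.sum()
    if total <= 0:
        raise ValueError("vector strength undefined: probabilities sum to zero")
    phase = 2.0 * np.pi * times / period
    vs = math.hypot(float(p @ np.cos(phase)), float(p @ np.sin(phase))) / total
    return float(min(vs, 1.0))


def probe_recovery_ratio(
    masked: SimulationResult,
    unmasked: SimulationResult,
    probe_window: tuple[float, float],
) -> float:
    """Masked over unmasked summed probe firing probability.

    Both runs must present the same probe pulses inside ``probe_window``;
    values below 1 indicate masking (refractoriness, adaptation,
    accommodation), values above 1 facilitation.
    """
    t0, t1 = probe_window

    def probe_mass(result: SimulationResult) -> float:
        return sum(r.p_s_total for r in result.responses if t0 <= r.t_start < t1)

    denom = probe_mass(unmasked)
    if denom <= 0:
        raise ValueError("probe recovery ratio undefined: unmasked probe mass is zero")
    return probe_mass(masked) / denom
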