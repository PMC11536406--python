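"""Response of one threshold path to one pulse.

Given the deterministic membrane potential and a threshold path, this
module computes, per pulse:

* the spike-cancellation offset ``o_cancel`` — the threshold increase that
  makes a biphasic pulse harder to fire than a monophasic one with the same
  leading phase (the charge-reversing second phase can abort an action
  potential whose initiation period of duration ``phi`` extends into it);
* the total firing probability, the maximum over the leading phase of
  Phi((V - (mu_theta + o_cancel)) / sigma_theta);
* the threshold-crossing time distribution (a cumulative-Gaussian fit to
  the crossing curve g(t), which excludes the cancellation offset);
* the amplitude-dependent latency and jitter (logistic functions of the
  headroom between V_max and the effective threshold);
* the Gaussian spike-time component, crossing time plus latency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, ndtr, ndtri

from .membrane import DEFAULT_GRID_STEP, MembranePotential
from .stimulus import BiphasicPulse
from .threshold_state import ThresholdComponent, ThresholdParams, evaluate

__all__ = [
    "LatencyParams",
    "CancellationResult",
    "SpikeTimeComponent",
    "PathResponse",
    "PulseResponse",
    "cancellation_offset",
    "firing_probability",
    "crossing_distribution",
    "latency_jitter",
    "spike_time_component",
    "component_response",
    "fit_cumulative_gaussian",
]

log = logging.getLogger(__name__)

#: crossing curves peaking below this carry no usable spike-time mass
G_FLOOR = 1e-9
#: paths with conditional firing probability at or below this are not branched
PS_FLOOR = 1e-12


@dataclass(frozen=True)
class LatencyParams:
    """Constants of the logistic latency/jitter laws (defaults are fitted values).

    ``l1``, ``l2`` (V) and ``l3``, ``l4`` (s) shape the mean latency;
    ``j1``, ``j2`` (V) and ``j3`` (s) the jitter.  Both decrease with the
    overshoot of the membrane potential above the effective threshold:
    latency from ``l3 + l4`` down to ``l4``, jitter from ``j3`` down to 0.
    """

    l1: float = 110e-6
    l2: float = 548e-6
    l3: float = 393e-6
    l4: float = 423e-6
    j1: float = 545e-6
    j2: float = 316e-6
    j3: float = 130e-6

    def __post_init__(self) -> None:
        for name in ("l1", "l2", "l3", "l4", "j1", "j2", "j3"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CancellationResult:
    """Spike-cancellation geometry for one pulse.

    ``phi`` is the action-potential initiation duration, ``phi_n_min`` the
    minimum part of it that must fall inside the excitatory phase,
    ``t_cancel`` the deadline by which the threshold must be crossed, and
    ``o_cancel`` the equivalent threshold offset (>= 0; 0 for monophasic
    pulses and for gaps longer than ``phi``).  ``v_max``/``t_of_max`` cache
    the leading-phase potential maximum.
    """

    phi: float
    phi_n_min: float
    t_cancel: float
    o_cancel: float
    v_max: float
    t_of_max: float


@dataclass(frozen=True)
class SpikeTimeComponent:
    """Gaussian spike-time component of one path: crossing time + latency."""

    weight: float
    mu_st: float
    sigma_st: float
    mu_ct: float
    sigma_ct: float
    mu_l: float
    sigma_l: float


@dataclass(frozen=True)
class PathResponse:
    """Per-path outcome of a pulse: conditional firing probability and, when
    the path can fire, its spike-time component (weight filled in later)."""

    path_index: int
    p_cond: float
    spike_time: SpikeTimeComponent | None
    mu_ct: float | None


@dataclass(frozen=True)
class PulseResponse:
    """Total response to one pulse across all threshold paths."""

    pulse_index: int
    t_start: float
    p_s_total: float
    per_path: tuple[PathResponse, ...]
    o_cancel: float
    v_max: float

    @property
    def spike_time_mixture(self) -> tuple[SpikeTimeComponent, ...]:
        """Spike-time components with weights normalized to sum to one."""
        comps = [pr.spike_time for pr in self.per_path if pr.spike_time is not None]
        total = sum(c.weight for c in comps)
        if total <= 0:
            return ()
        return tuple(
            SpikeTimeComponent(
                weight=c.weight / total,
                mu_st=c.mu_st,
                sigma_st=c.sigma_st,
                mu_ct=c.mu_ct,
                sigma_ct=c.sigma_ct,
                mu_l=c.mu_l,
                sigma_l=c.sigma_l,
            )
            for c in comps
        )


def cancellation_offset(
    pulse: BiphasicPulse, potential: MembranePotential, phi: float
) -> CancellationResult:
    """Threshold offset equivalent to spike cancellation by the second phase.

    The initiation period ``phi`` splits into a part inside the excitatory
    (leading, cathodic) phase, the interphase gap, and a part inside the
    counteracting phase.  Cancellation succeeds when the counteracting
    charge dominates, which fixes the minimum lead-in ``phi_n_min`` and a
    crossing deadline ``t_cancel = t_start + d_lead - phi_n_min``.  Since V
    rises strictly until the end of the cathodic phase, enforcing the
    deadline is equivalent to raising the threshold by
    ``o_cancel = V_max - V(t_cancel)``.

    No cancellation (offset 0) for monophasic pulses, zero-amplitude
    phases, or gaps with ``phi_n_min <= 0``.
    """
    if pulse.a_lead > 0:
        raise ValueError(
            "leading phase must be cathodic (non-positive current); a spike "
            "can only be evoked by a cathodic phase"
        )
    v_max, t_of_max = potential.max_in_window(pulse.t_start, pulse.t_lead_end)
    a_n = abs(pulse.a_lead)  # excitatory-phase magnitude
    a_p = abs(pulse.a_second)  # counteracting-phase magnitude
    if pulse.is_monophasic or a_p == 0.0 or a_n == 0.0:
        return CancellationResult(phi, 0.0, pulse.t_lead_end, 0.0, v_max, t_of_max)
    phi_n_min = (phi - pulse.d_ipg) / (1.0 + a_n / a_p)
    if phi_n_min <= 0.0:
        return CancellationResult(phi, phi_n_min, pulse.t_lead_end, 0.0, v_max, t_of_max)
    t_cancel = pulse.t_lead_end - phi_n_min
    o_cancel = max(v_max - float(potential(t_cancel)), 0.0)
    return CancellationResult(phi, phi_n_min, t_cancel, o_cancel, v_max, t_of_max)


def _window_grid(t0: float, t1: float, grid_step: float, extra: float | None = None) -> np.ndarray:
    """Uniform grid over [t0, t1] augmented with the exact window endpoints
    (and optionally the analytic time of V_max) so coarseness never clips a
    maximum."""
    n = int(math.floor((t1 - t0) / grid_step + 1e-9))
    pts = t0 + grid_step * np.arange(n + 1)
    tail = [t1] if pts[-1] < t1 - 1e-15 else []
    if extra is not None and t0 <= extra <= t1:
        tail.append(extra)
    if tail:
        pts = np.unique(np.concatenate([pts, np.asarray(tail)]))
    return pts


def _scores(v: np.ndarray, mu: np.ndarray, sigma: np.ndarray, offset: float) -> np.ndarray:
    """Standardized headroom (V - mu - offset)/sigma; -inf where mu is infinite."""
    out = np.full_like(v, -np.inf)
    finite = np.isfinite(mu)
    if np.any(finite):
        out[finite] = (v[finite] - mu[finite] - offset) / sigma[finite]
    return out


def firing_probability(
    potential: MembranePotential,
    component: ThresholdComponent,
    params: ThresholdParams,
    o_cancel: float,
    window: tuple[float, float],
    grid_step: float = DEFAULT_GRID_STEP,
) -> float:
    """Maximum over the window of Phi((V - (mu_theta + o_cancel)) / sigma_theta).

    The window is the leading-phase extent of the pulse.  Returns 0 when
    the whole window lies inside an absolute refractory period.
    """
    t0, t1 = window
    _, t_vmax = potential.max_in_window(t0, t1)
    times = _window_grid(t0, t1, grid_step, extra=t_vmax)
    v = np.asarray(potential(times))
    mu, sigma = evaluate(component, times, params)
    best = np.max(_scores(v, mu, sigma, o_cancel))
    return 0.0 if best == -np.inf else float(ndtr(best))


def fit_cumulative_gaussian(
    x: np.ndarray, y: np.ndarray, plateau: float
) -> tuple[float, float]:
    """Least-squares fit of ``plateau * Phi((x - mu)/sigma)`` returning (mu, sigma).

    A probit-scale linear regression provides the starting point (exact
    when y is exactly a scaled cumulative Gaussian); a bounded
    least-squares refinement follows.  If the refinement fails or the
    probit stage is degenerate, falls back to the quantile method (mu at
    half plateau, sigma from the Phi(+-1) quantiles) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if plateau <= 0:
        raise ValueError("plateau must be positive")
    z = y / plateau
    informative = (z > 1e-7) & (z < 1.0 - 1e-7)

    def quantile_estimate() -> tuple[float, float]:
        # x at which z first reaches a level, by linear interpolation
        def x_at(level: float) -> float:
            above = z >= level
            if not above.any():
                return float(x[-1])
            idx = int(np.argmax(above))
            if idx == 0:
                return float(x[0])
            z0, z1 = z[idx - 1], z[idx]
            if z1 == z0:
                return float(x[idx])
            return float(x[idx - 1] + (level - z0) / (z1 - z0) * (x[idx] - x[idx - 1]))

        mu = x_at(0.5)
        lo = x_at(float(ndtr(-1.0)))
        hi = x_at(float(ndtr(1.0)))
        sigma = max((hi - lo) / 2.0, 1e-12)
        return mu, sigma

    if np.count_nonzero(informative) >= 3:
        probit = ndtri(z[informative])
        sigma0, mu0 = np.polyfit(probit, x[informative], 1)
        if not (np.isfinite(sigma0) and sigma0 > 0):
            mu0, sigma0 = quantile_estimate()
    else:
        mu0, sigma0 = quantile_estimate()

    def residual(theta: np.ndarray) -> np.ndarray:
        mu, log_sigma = theta
        return plateau * ndtr((x - mu) / np.exp(log_sigma)) - y

    try:
        sol = least_squares(
            residual,
            x0=np.array([mu0, np.log(max(sigma0, 1e-12))]),
            method="lm",
            max_nfev=200,
        )
        if sol.success and np.all(np.isfinite(sol.x)):
            return float(sol.x[0]), float(np.exp(sol.x[1]))
    except Exception:  # pragma: no cover - scipy failure path
        pass
    log.warning("cumulative-Gaussian fit did not converge; using quantile estimate")
    return quantile_estimate()


def crossing_distribution(
    potential: MembranePotential,
    component: ThresholdComponent,
    params: ThresholdParams,
    window: tuple[float, float],
    grid_step: float = DEFAULT_GRID_STEP,
) -> tuple[float, float] | None:
    """Mean and s.d. of the threshold-crossing time over the pulse window.

    Fits ``a * Phi((t - mu_ct)/sigma_ct)`` to the crossing curve
    ``g(t) = Phi((V - mu_theta)/sigma_theta)`` with ``a`` pinned to the
    terminal plateau of g.  The cancellation offset is deliberately absent
    from g.  Returns None when g never rises above the floor (the path
    contributes no spike-time mass).
    """
    t0, t1 = window
    _, t_vmax = potential.max_in_window(t0, t1)
    times = _window_grid(t0, t1, grid_step, extra=t_vmax)
    v = np.asarray(potential(times))
    mu, sigma = evaluate(component, times, params)
    g = ndtr(_scores(v, mu, sigma, 0.0))
    plateau = float(g[-1])
    if float(np.max(g)) <= G_FLOOR or plateau <= G_FLOOR:
        return None
    return fit_cumulative_gaussian(times, g, plateau)


def latency_jitter(
    v_max: float,
    mu_theta_at_ct: float,
    o_cancel: float,
    params: LatencyParams,
) -> tuple[float, float]:
    """Mean latency and jitter as logistic functions of the threshold headroom.

    ``delta_v = v_max - (mu_theta(mu_ct) + o_cancel)`` is the overshoot of
    the potential above the effective threshold; both latency and jitter
    decrease monotonically with it (they keep shrinking even after the
    firing probability saturates at 1).
    """
    delta_v = v_max - (mu_theta_at_ct + o_cancel)
    mu_l = params.l3 * expit(-(delta_v - params.l1) / params.l2) + params.l4
    sigma_l = params.j3 * expit(-(delta_v - params.j1) / params.j2)
    return float(mu_l), float(sigma_l)


def spike_time_component(
    ct: tuple[float, float], lat: tuple[float, float], weight: float = 1.0
) -> SpikeTimeComponent:
    """Combine independent Gaussian crossing time and latency into the spike time."""
    mu_ct, sigma_ct = ct
    mu_l, sigma_l = lat
    if sigma_ct < 0 or sigma_l < 0:
        raise ValueError("standard deviations must be non-negative")
    return SpikeTimeComponent(
        weight=weight,
        mu_st=mu_ct + mu_l,
        sigma_st=math.hypot(sigma_ct, sigma_l),
        mu_ct=mu_ct,
        sigma_ct=sigma_ct,
        mu_l=mu_l,
        sigma_l=sigma_l,
    )


def component_response(
    pulse: BiphasicPulse,
    potential: MembranePotential,
    component: ThresholdComponent,
    thr: ThresholdParams,
    lat: LatencyParams,
    canc: CancellationResult,
    path_index: int = 0,
    grid_step: float = DEFAULT_GRID_STEP,
) -> PathResponse:
    """Full single-path response to one pulse (shared grid for all quantities).

    Computes the conditional firing probability and, when the path can fire
    (p above the branching floor), the crossing fit, latency and spike-time
    component.  When the crossing fit is unavailable but p is positive, the
    time of the window maximum stands in for mu_ct (logged).
    """
    window = (pulse.t_start, pulse.t_lead_end)
    times = _window_grid(*window, grid_step, extra=canc.t_of_max)
    v = np.asarray(potential(times))
    mu, sigma = evaluate(component, times, thr)
    scores = _scores(v, mu, sigma, canc.o_cancel)
    best = np.max(scores)
    p_cond = 0.0 if best == -np.inf else float(ndtr(best))
    if p_cond <= PS_FLOOR:
        return PathResponse(path_index=path_index, p_cond=p_cond, spike_time=None, mu_ct=None)

    g = ndtr(_scores(v, mu, sigma, 0.0))
    plateau = float(g[-1])
    if float(np.max(g)) > G_FLOOR and plateau > G_FLOOR:
        mu_ct, sigma_ct = fit_cumulative_gaussian(times, g, plateau)
    else:
        mu_ct = float(times[int(np.argmax(scores))])
        sigma_ct = 0.0
        log.debug(
            "crossing fit unavailable for path %d at pulse t=%g; using window max",
            path_index,
            pulse.t_start,
        )
    mu_at_ct, _ = evaluate(component, float(np.clip(mu_ct, times[0], times[-1])), thr)
    mu_l, sigma_l = latency_jitter(canc.v_max, mu_at_ct, canc.o_cancel, lat)
    st = spike_time_component((mu_ct, sigma_ct), (mu_l, sigma_l))
    return PathResponse(path_index=path_index, p_cond=p_cond, spike_time=st, mu_ct=mu_ct)
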