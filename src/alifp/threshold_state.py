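"""Gaussian-mixture firing threshold and its history-dependent modifiers.

The threshold of the fiber is not a number but a Gaussian distribution
N(mu_theta(t), sigma_theta(t)).  Each spike/no-spike history ("path")
carries its own trajectory of the mean and standard deviation, obtained by
multiplying the resting values by one factor per past stimulation event:

* ``fac_acc``     — facilitation followed by accommodation after a pulse
                    that did *not* fire, anchored at the end of that
                    pulse's leading phase;
* ``refractory``  — absolute + relative refractoriness after a spike,
                    anchored at the mean threshold-crossing time;
* ``adaptation``  — small, slow threshold build-up after a spike, same
                    anchor as refractoriness (the two are always created as
                    a pair).

Factors multiply commutatively on the baseline, so facilitation can
accumulate over repeated subthreshold pulses.  Three bounds keep the
composition physiological: the facilitation/accommodation product is
floored at ``f5``, the adaptation product is capped at ``a_max``, and the
standard deviation is capped at ``b * mu`` so that a fiber at rest (or in
recovery) never fires spontaneously with more than ~0.1% probability at
zero stimulus amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThresholdParams",
    "ModifierEvent",
    "ThresholdComponent",
    "ThresholdMixture",
    "fac_acc_curve",
    "refractory_curve",
    "adaptation_curve",
    "evaluate",
    "compress_events",
]

FAC_ACC = "fac_acc"
REFRACTORY = "refractory"
ADAPTATION = "adaptation"
_KINDS = (FAC_ACC, REFRACTORY, ADAPTATION)

# Horizons beyond which a modifier factor is indistinguishable from 1 and
# its event can be dropped (relative deviation < 1e-7 with the default
# constants).  Adaptation decays on a ~0.27 s scale and is kept much longer.
FAC_ACC_HORIZON = 30e-3
REFRACTORY_HORIZON = 60e-3
ADAPTATION_HORIZON = 6.0

#: weights must sum to one within this tolerance
WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class ThresholdParams:
    """Threshold-dynamics constants (defaults are the fitted values).

    ``m_theta``/``s_theta`` are the resting mean and s.d. of the threshold
    (V).  ``f1``/``f2`` (s), ``f3`` (-), ``f4`` (1/s) shape the combined
    facilitation/accommodation curve and ``f5`` floors its accumulated
    product.  ``t_arp`` is the absolute refractory period, ``tau_rrp`` the
    relative-refractory time constant, ``p``/``q`` shape the refractory
    recovery.  ``c_a`` is the per-spike adaptation increment, ``tau_a`` its
    time constant, and ``a_max`` caps the accumulated adaptation.  ``b``
    caps the relative spread (sigma <= b * mu).
    """

    m_theta: float = 10e-3
    s_theta: float = 0.43e-3
    f1: float = 0.1e-3
    f2: float = -1.4e-3
    f3: float = 0.45
    f4: float = 0.9e3
    f5: float = 0.5
    t_arp: float = 0.37e-3
    tau_rrp: float = 2.56e-3
    p: float = 0.377
    q: float = 0.102
    c_a: float = 0.015
    tau_a: float = 0.27
    a_max: float = 1.7
    b: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        positive = (
            "m_theta", "s_theta", "f1", "f3", "f4", "t_arp",
            "tau_rrp", "p", "q", "c_a", "tau_a", "b",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.f5 < 1:
            raise ValueError("f5 must be in (0, 1)")
        if not self.a_max >= 1:
            raise ValueError("a_max must be >= 1")
        if not math.isfinite(self.f2):
            raise ValueError("f2 must be finite")


@dataclass(frozen=True)
class ModifierEvent:
    """A single past stimulation outcome acting on a threshold path.

    ``anchor`` is the time the modifier clock starts: the end of the
    leading phase for ``fac_acc``, the mean crossing time for
    ``refractory`` and ``adaptation``.  Modifiers act only at times
    strictly after their anchor.
    """

    kind: str
    anchor: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown modifier kind {self.kind!r}")
        if not math.isfinite(self.anchor):
            raise ValueError("anchor must be finite")


@dataclass(frozen=True)
class ThresholdComponent:
    """One history path: a weight and its ordered modifier events."""

    weight: float
    events: tuple[ModifierEvent, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if not 0.0 <= self.weight <= 1.0 + WEIGHT_TOL:
            raise ValueError(f"weight must be in [0, 1], got {self.weight}")

    def anchors(self, kind: str) -> np.ndarray:
        return np.array([e.anchor for e in self.events if e.kind == kind], dtype=float)


@dataclass(frozen=True)
class ThresholdMixture:
    """Weighted set of threshold paths; weights sum to one."""

    components: tuple[ThresholdComponent, ...]
    k_max: int = 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if len(self.components) == 0:
            raise ValueError("mixture needs at least one component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mixture weights sum to {total}, expected 1")

    @classmethod
    def resting(cls, k_max: int = 20) -> "ThresholdMixture":
        return cls(components=(ThresholdComponent(weight=1.0),), k_max=k_max)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def normalized(self) -> "ThresholdMixture":
        total = sum(c.weight for c in self.components)
        if total <= 0:
            raise ValueError("cannot normalize a zero-mass mixture")
        comps = tuple(
            ThresholdComponent(weight=c.weight / total, events=c.events)
            for c in self.components
        )
        return ThresholdMixture(components=comps, k_max=self.k_max)


def fac_acc_curve(t_since, params: ThresholdParams):
    """Facilitation/accommodation factor F at ``t_since`` seconds past the anchor.

    F dips below one right after a subthreshold pulse (facilitation), rises
    above one for a few milliseconds (accommodation) and converges to one.
    """
    t = np.asarray(t_since, dtype=float)
    f = (1.0 - np.exp(-params.f4 * (t + params.f1))) * (
        1.0 + params.f3 * np.exp(-params.f4 * (t + params.f2))
    )
    return f if np.ndim(t_since) else float(f)


def refractory_curve(t_since, params: ThresholdParams):
    """Refractory factor R at ``t_since`` seconds past the crossing time.

    Infinite during the absolute refractory period (no spike possible),
    then a recovery that decreases toward one.
    """
    t = np.asarray(t_since, dtype=float)
    with np.errstate(over="ignore", divide="ignore"):
        denom = (1.0 - np.exp(-(t + params.t_arp) / (params.q * params.tau_rrp))) * (
            1.0 - params.p * np.exp(-(t + params.t_arp) / params.tau_rrp)
        )
        r = np.where(t < params.t_arp, np.inf, 1.0 / denom)
    return r if np.ndim(t_since) else float(r)


def adaptation_curve(t_since, params: ThresholdParams):
    """Adaptation factor A = 1 + c_a * exp(-t/tau_a); bounded in (1, 1 + c_a]."""
    t = np.asarray(t_since, dtype=float)
    a = 1.0 + params.c_a * np.exp(-t / params.tau_a)
    return a if np.ndim(t_since) else float(a)


_CURVES = {FAC_ACC: fac_acc_curve, REFRACTORY: refractory_curve, ADAPTATION: adaptation_curve}


def evaluate(
    component: ThresholdComponent, t, params: ThresholdParams
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and s.d. of one threshold path at time(s) ``t``.

    Composition: mu = m_theta * max(prod F, f5) * prod R * min(prod A, a_max),
    sigma built from s_theta with the same factors (floored at f5 likewise),
    then capped at ``b * mu``.  Inside an absolute refractory period mu is
    +inf (firing impossible); sigma is reported as the resting value there
    since it is immaterial.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))

    def product(kind: str) -> np.ndarray:
        anchors = component.anchors(kind)
        if anchors.size == 0:
            return np.ones_like(t_arr)
        dt = t_arr[None, :] - anchors[:, None]
        active = dt > 0
        factors = np.ones_like(dt)
        if np.any(active):
            factors[active] = _CURVES[kind](dt[active], params)
        return np.prod(factors, axis=0)

    fac = np.maximum(product(FAC_ACC), params.f5)
    ref = product(REFRACTORY)
    ada = np.minimum(product(ADAPTATION), params.a_max)

    mu = params.m_theta * fac * ref * ada
    sigma = params.s_theta * fac * ref * ada
    sigma = np.minimum(sigma, params.b * mu)
    infinite = ~np.isfinite(mu)
    if np.any(infinite):
        sigma = np.where(infinite, params.s_theta, sigma)
    if np.ndim(t) == 0:
        return float(mu[0]), float(sigma[0])
    return mu, sigma


def compress_events(
    events: tuple[ModifierEvent, ...], now: float
) -> tuple[ModifierEvent, ...]:
    """Drop events whose factor has fully recovered to 1 by time ``now``.

    A fac_acc or refractory event older than its horizon perturbs the
    threshold by less than ~1e-7 relative and only shrinks further; keeping
    the list short bounds the per-pulse cost of long simulations and lets
    equivalent paths merge.
    """
    horizon = {
        FAC_ACC: FAC_ACC_HORIZON,
        REFRACTORY: REFRACTORY_HORIZON,
        ADAPTATION: ADAPTATION_HORIZON,
    }
    return tuple(e for e in events if now - e.anchor <= horizon[e.kind])
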