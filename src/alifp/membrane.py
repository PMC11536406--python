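"""Passive membrane potential of the fiber under pulsatile current.

The membrane is a linear leaky integrator driven by the extracellular
stimulating current I(t),

    tau * dV/dt = -R * I(t) - V(t) + V_rest,

so a cathodic (negative) current with positive resistance depolarizes the
membrane.  Because every stimulus segment carries a constant current, the
ODE is solved exactly per segment:

    V(t0 + dt) = V_eq + (V(t0) - V_eq) * exp(-dt / tau),   V_eq = V_rest - R*I.

The potential is deterministic and shared by all threshold paths; it is
never reset by a spike.  A uniform grid (1 us by default) is used only for
reporting and for probability evaluation — values at arbitrary times come
from the closed form and are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus import PulseTrain

__all__ = ["MembraneParams", "MembranePotential", "MembraneTrace", "integrate", "window_max"]

#: default reporting / probability-evaluation grid step (s)
DEFAULT_GRID_STEP = 1e-6


@dataclass(frozen=True)
class MembraneParams:
    """Leaky-integrator constants: time constant tau (s), resistance R (Ohm),
    resting potential (V).

    A negative resistance flips the sign convention and can be used to treat
    anodic stimulation as excitatory; the default describes cathodic
    excitation.
    """

    tau: float = 120e-6
    resistance: float = 28.99
    v_rest: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.resistance == 0:
            raise ValueError("resistance must be non-zero")


class MembranePotential:
    """Exact piecewise-exponential solution of the leaky integrator.

    Stores the breakpoints of the piecewise-constant current together with
    the potential at each breakpoint; evaluation anywhere is closed-form.
    The current is zero after the last breakpoint, so the potential decays
    toward rest there.
    """

    def __init__(self, t_knots: np.ndarray, i_segments: np.ndarray, params: MembraneParams):
        t_knots = np.asarray(t_knots, dtype=float)
        i_segments = np.asarray(i_segments, dtype=float)
        if t_knots.ndim != 1 or len(t_knots) != len(i_segments) + 1:
            raise ValueError("need len(t_knots) == len(i_segments) + 1")
        if np.any(np.diff(t_knots) < 0):
            raise ValueError("t_knots must be non-decreasing")
        self.params = params
        self.t_knots = t_knots
        self.i_segments = i_segments
        # V at each knot, by exact forward recursion from rest
        v = np.empty(len(t_knots))
        v[0] = params.v_rest
        v_eq = params.v_rest - params.resistance * i_segments
        decay = np.exp(-np.diff(t_knots) / params.tau)
        for j in range(len(i_segments)):
            v[j + 1] = v_eq[j] + (v[j] - v_eq[j]) * decay[j]
        self.v_knots = v
        self._v_eq = v_eq

    @classmethod
    def from_train(cls, train: PulseTrain, params: MembraneParams) -> "MembranePotential":
        knots = [0.0]
        currents = []
        t = 0.0
        for p in train.pulses:
            if p.t_start > t:
                currents.append(0.0)
                knots.append(p.t_start)
            segs = [(p.d_lead, p.a_lead)]
            if p.d_ipg > 0:
                segs.append((p.d_ipg, 0.0))
            if p.d_second > 0:
                segs.append((p.d_second, p.a_second))
            for dur, amp in segs:
                currents.append(amp)
                knots.append(knots[-1] + dur)
            t = knots[-1]
        return cls(np.asarray(knots), np.asarray(currents), params)

    def __call__(self, t) -> np.ndarray | float:
        """Exact potential at time(s) ``t`` (scalar in, scalar out)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        tau = self.params.tau
        v_rest = self.params.v_rest
        out = np.empty_like(t_arr)
        # before the first knot: at rest
        before = t_arr <= self.t_knots[0]
        out[before] = v_rest
        # after the last knot: free decay toward rest
        after = t_arr >= self.t_knots[-1]
        out[after] = v_rest + (self.v_knots[-1] - v_rest) * np.exp(
            -(t_arr[after] - self.t_knots[-1]) / tau
        )
        mid = ~(before | after)
        if np.any(mid):
            seg = np.searchsorted(self.t_knots, t_arr[mid], side="right") - 1
            v0 = self.v_knots[seg]
            veq = self._v_eq[seg]
            out[mid] = veq + (v0 - veq) * np.exp(-(t_arr[mid] - self.t_knots[seg]) / tau)
        return out if np.ndim(t) else float(out[0])

    def max_in_window(self, t0: float, t1: float) -> tuple[float, float]:
        """Exact maximum of V over [t0, t1] and the (earliest) time it occurs.

        Within a constant-current segment V approaches its equilibrium
        monotonically, so the maximum over any window is attained at a
        segment boundary or a window edge; no grid is involved.
        """
        if not t0 < t1:
            raise ValueError("empty window: need t0 < t1")
        inner = self.t_knots[(self.t_knots > t0) & (self.t_knots < t1)]
        candidates = np.concatenate(([t0], inner, [t1]))
        values = self(candidates)
        best = int(np.argmax(values))  # argmax returns the first maximizer: earliest tie wins
        return float(values[best]), float(candidates[best])


@dataclass(frozen=True)
class MembraneTrace:
    """Sampled potential on a uniform grid plus the exact evaluator behind it."""

    times: np.ndarray
    v: np.ndarray
    potential: MembranePotential = field(repr=False)
    grid_step: float = DEFAULT_GRID_STEP


def integrate(
    train: PulseTrain,
    params: MembraneParams,
    grid_step: float = DEFAULT_GRID_STEP,
    t_end: float | None = None,
) -> MembraneTrace:
    """Solve the leaky integrator for a pulse train and sample it on a grid.

    The samples are exact (closed-form) values; ``grid_step`` affects only
    the reporting resolution, not accuracy.
    """
    if not grid_step > 0:
        raise ValueError("grid_step must be positive")
    potential = MembranePotential.from_train(train, params)
    if t_end is None:
        t_end = max(train.duration, float(potential.t_knots[-1]))
    times = np.arange(0.0, t_end + 0.5 * grid_step, grid_step)
    return MembraneTrace(times=times, v=potential(times), potential=potential, grid_step=grid_step)


def window_max(trace: MembraneTrace, t0: float, t1: float) -> tuple[float, float]:
    """Exact (v_max, t_of_max) of the trace's potential over [t0, t1]."""
    return trace.potential.max_in_window(t0, t1)
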