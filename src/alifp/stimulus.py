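"""Rectangular biphasic pulse trains: construction, modulation, level conversion, I/O.

Conventions
-----------
* Time is in seconds, current in amperes throughout the package.
* Current is signed; cathodic (excitatory, extracellular) current is
  *negative*.  The unsigned phase amplitudes used by the spike-cancellation
  algebra are derived from the signed fields where needed.
* A monophasic pulse is encoded as a biphasic pulse whose second phase has
  zero duration (and zero amplitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
import pandas as pd

__all__ = [
    "BiphasicPulse",
    "PulseTrain",
    "ModulationSpec",
    "make_train",
    "apply_modulation",
    "db_re_ref",
    "amp_from_db",
    "read_train_csv",
    "write_train_csv",
    "train_from_config",
]

#: column order of the pulse-train CSV interface (units in the names)
TRAIN_CSV_COLUMNS = (
    "t_start_s",
    "a_lead_A",
    "d_lead_s",
    "d_ipg_s",
    "a_second_A",
    "d_second_s",
)


@dataclass(frozen=True)
class BiphasicPulse:
    """One rectangular biphasic current pulse.

    Parameters
    ----------
    t_start : float
        Onset of the leading phase (s).
    a_lead : float
        Signed amplitude of the leading phase (A); cathodic is negative.
    d_lead : float
        Duration of the leading phase (s); must be positive.
    d_ipg : float
        Interphase gap (s); zero means the phases abut.
    a_second : float
        Signed amplitude of the second phase (A).
    d_second : float
        Duration of the second phase (s); zero encodes a monophasic pulse.
    """

    t_start: float
    a_lead: float
    d_lead: float
    d_ipg: float = 0.0
    a_second: float = 0.0
    d_second: float = 0.0

    def __post_init__(self) -> None:
        if not self.d_lead > 0:
            raise ValueError(f"d_lead must be positive, got {self.d_lead}")
        if self.d_second < 0:
            raise ValueError(f"d_second must be >= 0, got {self.d_second}")
        if self.d_ipg < 0:
            raise ValueError(f"d_ipg must be >= 0, got {self.d_ipg}")
        for name in ("t_start", "a_lead", "a_second"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def footprint(self) -> float:
        """Total extent of the pulse: both phases plus the gap (s)."""
        return self.d_lead + self.d_ipg + self.d_second

    @property
    def t_end(self) -> float:
        return self.t_start + self.footprint

    @property
    def t_lead_end(self) -> float:
        """End of the leading phase — the firing-probability window closes here."""
        return self.t_start + self.d_lead

    @property
    def is_monophasic(self) -> bool:
        return self.d_second == 0.0 or self.a_second == 0.0

    def scaled(self, factor: float) -> "BiphasicPulse":
        """Return a copy with both phase amplitudes multiplied by ``factor``."""
        return replace(self, a_lead=self.a_lead * factor, a_second=self.a_second * factor)

    def at(self, t_start: float) -> "BiphasicPulse":
        """Return a copy shifted to a new onset time."""
        return replace(self, t_start=t_start)


@dataclass(frozen=True)
class PulseTrain:
    """An ordered, non-overlapping sequence of biphasic pulses."""

    pulses: tuple[BiphasicPulse, ...]
    duration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pulses", tuple(self.pulses))
        for prev, nxt in zip(self.pulses, self.pulses[1:]):
            if nxt.t_start < prev.t_end - 1e-15:
                raise ValueError(
                    f"pulses overlap: pulse at {nxt.t_start} s starts before "
                    f"the previous pulse ends at {prev.t_end} s"
                )
        if self.duration < 0:
            raise ValueError("duration must be non-negative")

    def __len__(self) -> int:
        return len(self.pulses)

    def __iter__(self):
        return iter(self.pulses)


@dataclass(frozen=True)
class ModulationSpec:
    """Sinusoidal amplitude modulation: depth ``m`` and frequency ``f_m`` (Hz)."""

    m: float
    f_m: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"modulation depth must be in [0, 1], got {self.m}")
        if not self.f_m > 0:
            raise ValueError(f"modulation frequency must be positive, got {self.f_m}")


def make_train(rate_pps: float, duration: float, shape: BiphasicPulse) -> PulseTrain:
    """Build a uniform pulse train from a template pulse.

    Places ``floor(duration * rate_pps)`` copies of ``shape`` at a uniform
    period ``1/rate_pps`` starting at t = 0.  Rejects configurations where
    the pulse footprint does not fit into the period.
    """
    if not rate_pps > 0:
        raise ValueError("rate_pps must be positive")
    if not duration > 0:
        raise ValueError("duration must be positive")
    period = 1.0 / rate_pps
    if shape.footprint > period + 1e-15:
        raise ValueError(
            f"pulse footprint {shape.footprint:g} s exceeds the pulse period "
            f"{period:g} s at {rate_pps:g} pps"
        )
    # small epsilon guards against duration*rate landing just below an integer
    n = int(math.floor(duration * rate_pps + 1e-9))
    pulses = tuple(shape.at(i * period) for i in range(n))
    return PulseTrain(pulses=pulses, duration=duration)


def apply_modulation(train: PulseTrain, mod: ModulationSpec) -> PulseTrain:
    """Scale each pulse by the sinusoidal envelope sampled at its onset.

    The envelope ``1 + m*sin(2*pi*f_m*t)`` is evaluated once per pulse at
    ``t_start``; phase durations are much shorter than any modulation period
    of interest, so a single scale factor per pulse suffices.  Timing is
    unchanged.
    """
    pulses = tuple(
        p.scaled(1.0 + mod.m * math.sin(2.0 * math.pi * mod.f_m * p.t_start))
        for p in train.pulses
    )
    return PulseTrain(pulses=pulses, duration=train.duration)


def db_re_ref(amplitude: float, reference: float) -> float:
    """Current level in dB re a reference amplitude: ``20*log10(a/ref)``.

    Operates on magnitudes; both inputs must be positive.
    """
    if not amplitude > 0 or not reference > 0:
        raise ValueError("amplitude and reference must be positive magnitudes")
    return 20.0 * math.log10(amplitude / reference)


def amp_from_db(level_db: float, reference: float) -> float:
    """Inverse of :func:`db_re_ref`: amplitude magnitude at ``level_db`` re ``reference``."""
    if not reference > 0:
        raise ValueError("reference must be a positive magnitude")
    return reference * 10.0 ** (level_db / 20.0)


def write_train_csv(train: PulseTrain, path: str | Path) -> None:
    """Write a pulse train to CSV with explicit unit-suffixed headers."""
    df = pd.DataFrame(
        {
            "t_start_s": [p.t_start for p in train.pulses],
            "a_lead_A": [p.a_lead for p in train.pulses],
            "d_lead_s": [p.d_lead for p in train.pulses],
            "d_ipg_s": [p.d_ipg for p in train.pulses],
            "a_second_A": [p.a_second for p in train.pulses],
            "d_second_s": [p.d_second for p in train.pulses],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_train_csv(path: str | Path, duration: float | None = None) -> PulseTrain:
    """Read a pulse train written by :func:`write_train_csv`.

    ``duration`` defaults to the end of the last pulse.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRAIN_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pulse-train CSV is missing columns: {missing}")
    pulses = tuple(
        BiphasicPulse(
            t_start=row.t_start_s,
            a_lead=row.a_lead_A,
            d_lead=row.d_lead_s,
            d_ipg=row.d_ipg_s,
            a_second=row.a_second_A,
            d_second=row.d_second_s,
        )
        for row in df.itertuples()
    )
    if duration is None:
        duration = pulses[-1].t_end if pulses else 0.0
    return PulseTrain(pulses=pulses, duration=duration)


def train_from_config(cfg: dict) -> PulseTrain:
    """Build a (possibly modulated) uniform train from a config mapping.

    Recognised keys: ``rate_pps, duration_s, phase_s, ipg_s, amplitude_A,
    polarity, second_phase_s, modulation {m, fm_hz}``.  ``polarity`` is
    ``"cathodic"`` (default) or ``"anodic"`` and fixes the sign of the
    leading phase; the second phase gets the opposite sign and, unless
    ``second_phase_s`` is given, the same duration.
    """
    known = {
        "rate_pps",
        "duration_s",
        "phase_s",
        "ipg_s",
        "amplitude_A",
        "polarity",
        "second_phase_s",
        "modulation",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown stimulus config keys: {sorted(unknown)}")
    polarity = cfg.get("polarity", "cathodic")
    if polarity not in ("cathodic", "anodic"):
        raise ValueError(f"polarity must be 'cathodic' or 'anodic', got {polarity!r}")
    sign = -1.0 if polarity == "cathodic" else 1.0
    amplitude = float(cfg["amplitude_A"])
    if amplitude < 0:
        raise ValueError("amplitude_A is a magnitude; use 'polarity' for the sign")
    phase = float(cfg["phase_s"])
    second = float(cfg.get("second_phase_s", phase))
    shape = BiphasicPulse(
        t_start=0.0,
        a_lead=sign * amplitude,
        d_lead=phase,
        d_ipg=float(cfg.get("ipg_s", 0.0)),
        a_second=-sign * amplitude if second > 0 else 0.0,
        d_second=second,
    )
    train = make_train(float(cfg["rate_pps"]), float(cfg["duration_s"]), shape)
    mod_cfg = cfg.get("modulation")
    if mod_cfg:
        mod = ModulationSpec(m=float(mod_cfg["m"]), f_m=float(mod_cfg["fm_hz"]))
        train = apply_modulation(train, mod)
    return train
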