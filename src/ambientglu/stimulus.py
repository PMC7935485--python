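"""Stimulus-train generation: constant-rate bursts and the in-vivo-like
sinusoidally frequency-modulated protocol.

The modulated protocol emulates vestibular-style mossy-fiber firing: a
5 s silence, 10 s of conditioning at the 26 Hz carrier rate, then 10 s in
which the instantaneous rate is modulated as

    rate(t) = carrier + d * cos(2 pi f t)

(f the modulation frequency in Hz, d the modulation depth in Hz), i.e. the
stimulus phase is phi(t) = 2 pi carrier t + (d/f) sin(2 pi f t) and events
fall at integer-cycle crossings of phi.  The depth/frequency pairs used
are (6, 0.3), (40, 1) and (120, 3) Hz.  With d > carrier the instantaneous
rate goes negative over part of the cycle; the phase then retreats and no
events are emitted until it first crosses a not-yet-visited cycle boundary
going forward.

Event times are in ms, generation is fully deterministic, and trains
round-trip through one-time-per-line text files importable by acquisition
software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = ["StimulusSpec", "StimulusTrain", "constant_train", "fm_train",
           "full_protocol", "write_train", "read_train"]

#: modulation depth (Hz) paired with each modulation frequency (Hz)
DEPTH_FOR_FMOD = {0.3: 6.0, 1.0: 40.0, 3.0: 120.0}


@dataclass(frozen=True)
class StimulusSpec:
    """Protocol description for the frequency-modulated train.

    The modulator starts at its maximum (cosine convention), so the
    modulated segment begins at rate ``carrier + depth``.
    """

    carrier: float = 26.0        # Hz
    f_mod: float = 1.0           # Hz
    depth: float = 40.0          # Hz
    silence_s: float = 5.0
    conditioning_s: float = 10.0
    modulated_s: float = 10.0

    def __post_init__(self):
        if self.carrier <= 0 or self.f_mod <= 0:
            raise ValueError("carrier and f_mod must be > 0")
        if min(self.silence_s, self.conditioning_s, self.modulated_s) < 0:
            raise ValueError("segment durations must be >= 0")

    @property
    def t_mod_start_ms(self) -> float:
        """Start of the modulated segment on the protocol time base."""
        return 1000.0 * (self.silence_s + self.conditioning_s)

    def instantaneous_rate(self, t_rel_ms) -> np.ndarray:
        """Rate (Hz) at time t_rel_ms after modulation onset (may be < 0)."""
        t = np.asarray(t_rel_ms, dtype=float) / 1000.0
        return self.carrier + self.depth * np.cos(2 * np.pi * self.f_mod * t)

    def phase_deg(self, t_ms) -> np.ndarray:
        """Stimulus phase in degrees (protocol time base, ms).

        The rate peak is at 90 deg and the rate trough at 270 deg: the
        cosine modulator peaks at modulation onset, which is mapped to 90.
        """
        t_rel = (np.asarray(t_ms, dtype=float) - self.t_mod_start_ms) / 1000.0
        return (90.0 + 360.0 * self.f_mod * t_rel) % 360.0


@dataclass(frozen=True)
class StimulusTrain:
    """Sorted event times (ms) plus the protocol that produced them."""

    event_times: np.ndarray
    spec: StimulusSpec | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", t)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("event times must be nonnegative and strictly increasing")

    def __len__(self) -> int:
        return self.event_times.size

    def shifted(self, offset_ms: float) -> "StimulusTrain":
        return StimulusTrain(self.event_times + offset_ms, self.spec, dict(self.meta))


def constant_train(rate_hz: float, n_or_duration, start_ms: float = 0.0,
                   duration: bool = False) -> StimulusTrain:
    """Evenly spaced events at 1000/rate ms intervals.

    ``n_or_duration`` is an event count, or a duration in seconds when
    ``duration=True`` (events at start, start+isi, ... while t < end).
    """
    if rate_hz <= 0:
        raise ValueError("rate must be > 0")
    isi = 1000.0 / rate_hz
    if duration:
        n = int(np.floor(n_or_duration * 1000.0 / isi - 1e-9)) + 1
    else:
        n = int(n_or_duration)
    return StimulusTrain(start_ms + isi * np.arange(n),
                         meta={"kind": "constant", "rate_hz": rate_hz})


def _phase_cycles(spec: StimulusSpec, t_ms: np.ndarray) -> np.ndarray:
    """phi(t)/2pi in cycles at time t_ms after modulation onset."""
    t = t_ms / 1000.0
    return spec.carrier * t + spec.depth / (2 * np.pi * spec.f_mod) \
        * np.sin(2 * np.pi * spec.f_mod * t)


def fm_train(spec: StimulusSpec, grid_dt_ms: float = 0.05) -> StimulusTrain:
    """Event times of the modulated segment (relative to its onset, ms).

    Events are the first forward crossings of integer cycle counts of the
    stimulus phase; cycle boundaries revisited after a phase retreat emit
    no second event.  An event falls at t=0 (the phase starts there at
    cycle 0, continuing the conditioning rhythm).
    """
    dur = spec.modulated_s * 1000.0
    tg = np.arange(0.0, dur + grid_dt_ms, grid_dt_ms)
    phase = _phase_cycles(spec, tg)
    run_max = np.maximum.accumulate(phase)
    events = [0.0]
    next_n = 1
    for i in range(1, tg.size):
        while run_max[i] >= next_n and run_max[i - 1] < next_n:
            # refine the crossing inside [tg[i-1], tg[i]] (phase increasing)
            t_ev = brentq(lambda t: float(_phase_cycles(spec, np.asarray(t))) - next_n,
                          tg[i - 1], tg[i], xtol=1e-7)
            if t_ev < dur:
                events.append(float(t_ev))
            next_n += 1
    return StimulusTrain(np.asarray(events), spec=spec,
                         meta={"kind": "fm",
                               "rate_convention": "carrier + depth*cos(2*pi*f_mod*t)"})


def full_protocol(spec: StimulusSpec = StimulusSpec()) -> StimulusTrain:
    """Silence, conditioning at the carrier rate, then the modulated train,
    concatenated on one continuous time base (ms)."""
    t0 = spec.silence_s * 1000.0
    cond = constant_train(spec.carrier, spec.conditioning_s, start_ms=t0, duration=True)
    mod = fm_train(spec).shifted(spec.t_mod_start_ms)
    times = np.concatenate([cond.event_times, mod.event_times])
    return StimulusTrain(times, spec=spec, meta={"kind": "full_protocol"})


def write_train(train: StimulusTrain, path) -> None:
    """One event time (ms) per line, fixed 1 us precision; importable as an
    acquisition-software event list."""
    with open(path, "w") as fh:
        fh.write("# event_time_ms\n")
        for t in train.event_times:
            fh.write(f"{t:.3f}\n")


def read_train(path) -> StimulusTrain:
    times = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            times.append(float(line))
    arr = np.asarray(times)
    if arr.size and np.any(np.diff(arr) <= 0):
        raise ValueError(f"{path}: event times not strictly increasing")
    return StimulusTrain(arr)
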