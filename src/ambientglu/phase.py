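"""Spike timing relative to the frequency-modulated stimulus.

Spikes recorded during the modulated segment are folded over modulation
cycles into a peristimulus time histogram (PSTH) on a phase axis where the
peak stimulus rate is 90 degrees and the slowest rate 270 degrees.  A sine
with a free number of cycles per stimulus period is fit to the PSTH; cells
that fire at both the rising (onset) and falling (offset) flank of the
cycle are captured by ~2 cycles per period, cells that fire through the
whole slow half by ~1.  The phase of the fitted-curve maximum in the
offset half of the cycle (90-360 deg) quantifies the timing of the offset
response, and a phase difference converts to a time delay via
delay_ms = delta_deg / 360 * 1000 / f_mod.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .stimulus import StimulusSpec

__all__ = ["CyclePSTH", "SineFit", "build_psth", "fit_sine",
           "offset_peak_phase", "phase_to_delay"]


@dataclass(frozen=True)
class CyclePSTH:
    """Cycle-folded PSTH on the 90deg-at-peak-rate phase axis."""

    bin_centers: np.ndarray       # degrees in [0, 360)
    rate: np.ndarray              # spikes/s per bin
    n_cycles: int
    n_sweeps: int
    f_mod: float                  # Hz
    n_spikes: int = 0

    def __post_init__(self):
        if np.any(self.rate < 0):
            raise ValueError("PSTH rates must be >= 0")


@dataclass(frozen=True)
class SineFit:
    """offset + amplitude * sin(2 pi * cycles_per_period * theta/360 + phase0)"""

    amplitude: float              # spikes/s, >= 0
    cycles_per_period: float
    phase0: float                 # degrees in [0, 360)
    offset: float                 # spikes/s
    goodness: float               # residual 2-norm
    flat: bool = False            # amplitude indistinguishable from 0

    def predict(self, theta_deg) -> np.ndarray:
        th = np.asarray(theta_deg, dtype=float)
        return self.offset + self.amplitude * np.sin(
            2 * np.pi * self.cycles_per_period * th / 360.0 + np.deg2rad(self.phase0))


def build_psth(spike_times, stimulus_spec: StimulusSpec, bin_deg: float = 10.0,
               n_sweeps: int = 1) -> CyclePSTH:
    """Fold spikes from the modulated segment into a phase histogram.

    ``spike_times`` are in ms on the protocol time base (one or several
    concatenated sweeps' worth; pass ``n_sweeps`` for correct rate
    normalization).  Spikes outside the modulated segment are ignored;
    spikes during silent (negative-rate) parts of the cycle fold normally.
    """
    if 360.0 % bin_deg != 0:
        raise ValueError("bin_deg must divide 360")
    spikes = np.asarray(spike_times, dtype=float)
    t0 = stimulus_spec.t_mod_start_ms
    t1 = t0 + stimulus_spec.modulated_s * 1000.0
    spikes = spikes[(spikes >= t0) & (spikes < t1)]
    n_cycles = int(round(stimulus_spec.modulated_s * stimulus_spec.f_mod))
    if n_cycles < 1:
        raise ValueError("modulated segment shorter than one modulation cycle")
    theta = stimulus_spec.phase_deg(spikes)
    nbins = int(round(360.0 / bin_deg))
    counts, edges = np.histogram(theta, bins=nbins, range=(0.0, 360.0))
    bin_time_s = (bin_deg / 360.0) / stimulus_spec.f_mod * n_cycles * n_sweeps
    return CyclePSTH(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        rate=counts / bin_time_s,
        n_cycles=n_cycles, n_sweeps=n_sweeps,
        f_mod=stimulus_spec.f_mod, n_spikes=int(spikes.size),
    )


def fit_sine(psth: CyclePSTH, max_cycles: float = 4.0) -> SineFit:
    """Least-squares sine fit with a free cycles-per-period.

    The objective is multimodal in (cycles_per_period, phase0); fits start
    from a grid of cycle counts (0.5 .. max_cycles) with the phase seeded
    by the circular mean of the residual structure, and the best residual
    norm wins.  A flat PSTH yields an amplitude ~0 fit flagged ``flat``.
    """
    th = np.asarray(psth.bin_centers, dtype=float)
    y = np.asarray(psth.rate, dtype=float)
    if th.size < 8:
        raise ValueError("need at least 8 PSTH bins for a sine fit")
    mean = float(y.mean())
    spread = float(y.std())
    if spread == 0.0:
        return SineFit(0.0, 1.0, 0.0, mean, 0.0, flat=True)

    def model(p, th):
        off, amp, k, ph = p
        return off + amp * np.sin(2 * np.pi * k * th / 360.0 + ph)

    best = None
    for k0 in np.arange(0.5, max_cycles + 0.25, 0.5):
        # linear least squares for (offset, a, b) at fixed k seeds amp/phase
        s = np.sin(2 * np.pi * k0 * th / 360.0)
        c = np.cos(2 * np.pi * k0 * th / 360.0)
        coef, *_ = np.linalg.lstsq(np.column_stack([np.ones_like(th), s, c]), y, rcond=None)
        amp0 = float(np.hypot(coef[1], coef[2]))
        ph0 = float(np.arctan2(coef[2], coef[1]))
        sol = least_squares(
            lambda p: model(p, th) - y,
            x0=[coef[0], max(amp0, 1e-3 * spread), k0, ph0],
            bounds=([-np.inf, 0.0, 0.25, -2 * np.pi],
                    [np.inf, np.inf, max_cycles + 0.5, 4 * np.pi]),
            xtol=1e-12, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    off, amp, k, ph = best.x
    return SineFit(
        amplitude=float(amp),
        cycles_per_period=float(k),
        phase0=float(np.rad2deg(ph) % 360.0),
        offset=float(off),
        goodness=float(np.sqrt(2 * best.cost)),
        flat=bool(amp < 1e-3 * max(spread, 1e-12)),
    )


def offset_peak_phase(fit: SineFit, window=(90.0, 360.0)) -> float:
    """Phase (deg) of the fitted-curve maximum in the offset half-cycle.

    The offset response is firing as the stimulus decelerates, i.e. in the
    90-360 deg window; the maximum is read from the fitted curve rather
    than raw bins.
    """
    if fit.flat:
        raise ValueError("flat PSTH: no offset-response peak")
    th = np.arange(window[0], window[1], 0.01)
    return float(th[int(np.argmax(fit.predict(th)))])


def phase_to_delay(delta_deg: float, f_mod: float) -> float:
    """Convert a phase difference (deg) at modulation frequency f_mod (Hz)
    to a time delay in ms: delta/360 * 1000/f_mod."""
    if f_mod <= 0:
        raise ValueError("f_mod must be > 0")
    return delta_deg / 360.0 * 1000.0 / f_mod
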