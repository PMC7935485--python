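"""Synthetic data with known ground truth for every pipeline stage.

Emulates (a) averaged whole-cell voltage-clamp recordings of UBC AMPAR
currents — forward-model current plus band-limited Gaussian noise, a leak
offset, and brief stimulation artifacts at each shock — and (b) spike
trains during the frequency-modulated stimulus with controllable onset
(near 90 deg) and offset firing components.

Noise is white at the acquisition rate and scaled so that its standard
deviation *after* the 1 kHz zero-phase analysis filter equals ``noise_sd``
— the bandwidth the fit actually sees.  The default 2 pA (post-filter,
per trial) is a typical baseline for whole-cell UBC recordings.

Paired control / transporter-block conditions are generated from one cell
by fold changes of the ground-truth parameters; the defaults (ambient
x2.4, released glutamate x2.3) are the cohort-mean fold changes this kind
of experiment reports, with the conductance fold at 1 (the no-extra-
spillover case).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .fitting import lowpass, simulate_current
from .glutamate import TransientParams
from .kinetics import RateScheme, VoltageParams
from .stimulus import StimulusSpec
from .trace import Trace

__all__ = ["SyntheticCellSpec", "SyntheticRecording", "generate_recording",
           "generate_cohort", "generate_spike_response", "COHORT_CENTERS"]

#: cohort-center ground truth: ambient uM, molecules/event, um, nS
COHORT_CENTERS = {"ambient": 4.7, "M": 5.0e6, "r": 1.23, "g_max": 10.0}


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Ground truth and recording-chain settings for one synthetic cell."""

    transient: TransientParams = field(
        default_factory=lambda: TransientParams(
            M=COHORT_CENTERS["M"], r=COHORT_CENTERS["r"],
            ambient=COHORT_CENTERS["ambient"]))
    g_max: float = COHORT_CENTERS["g_max"]      # nS
    leak_offset: float = -20.0                  # pA
    ambient_fold: float = 2.4
    M_fold: float = 2.3
    gmax_fold: float = 1.0
    noise_sd: float = 2.0        # pA, per trial, after the analysis filter
    n_trials: int = 6
    sampling_khz: float = 20.0
    analysis_filter_hz: float = 1000.0
    artifact_amp: float = 2000.0  # pA; 0 disables stimulation artifacts
    artifact_ms: float = 0.5      # artifact duration after each shock
    seed: int = 0

    def __post_init__(self):
        if min(self.ambient_fold, self.M_fold, self.gmax_fold) <= 0:
            raise ValueError("fold changes must be > 0")
        if self.noise_sd < 0 or self.n_trials < 1:
            raise ValueError("noise_sd must be >= 0 and n_trials >= 1")

    def block_transient(self) -> TransientParams:
        return dataclasses.replace(
            self.transient,
            ambient=self.transient.ambient * self.ambient_fold,
            M=self.transient.M * self.M_fold)


@dataclass
class SyntheticRecording:
    """Paired condition traces plus the serialized ground truth."""

    trials: dict            # condition -> list[Trace] (raw, noisy)
    artifact_windows: tuple  # (start_ms, stop_ms) per stimulus
    truth: dict             # ground-truth record incl. folds and seed


def _noise_gain(fs_khz: float, cutoff_hz: float, n: int = 8192) -> float:
    """sd gain of the zero-phase analysis filter on white noise."""
    imp = np.zeros(n)
    imp[n // 2] = 1.0
    return float(np.sqrt(np.sum(lowpass(imp, fs_khz, cutoff_hz) ** 2)))


def generate_recording(spec: SyntheticCellSpec, train, scheme: RateScheme,
                       volts: VoltageParams = VoltageParams(),
                       t0: float = 0.0, t_end: float | None = None) -> SyntheticRecording:
    """Forward-simulate paired control / transporter-block recordings.

    Per condition, ``spec.n_trials`` raw traces at the acquisition rate:
    noiseless model current + leak + white noise (scaled to ``noise_sd``
    after the analysis filter) + stimulation artifacts.  Deterministic for
    a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    events = np.asarray(getattr(train, "event_times", train), dtype=float)
    sd_acq = 0.0
    if spec.noise_sd > 0:
        sd_acq = spec.noise_sd / _noise_gain(spec.sampling_khz, spec.analysis_filter_hz)

    conditions = {
        "control": (spec.transient, spec.g_max),
        "block": (spec.block_transient(), spec.g_max * spec.gmax_fold),
    }
    trials: dict = {}
    for cond, (tp, gmax) in conditions.items():
        clean = simulate_current(
            dataclasses.replace(scheme, g_max=gmax), tp, events, volts,
            leak_offset=spec.leak_offset, t0=t0, t_end=t_end,
            fs_khz=spec.sampling_khz, method="grid")
        cond_trials = []
        for k in range(spec.n_trials):
            v = clean.values.copy()
            if sd_acq > 0:
                v = v + rng.normal(0.0, sd_acq, v.size)
            if spec.artifact_amp > 0:
                t = clean.times
                for ev in events:
                    w = (t >= ev) & (t < ev + spec.artifact_ms)
                    # biphasic shock artifact
                    v[w] += spec.artifact_amp * np.where(
                        t[w] < ev + spec.artifact_ms / 2, 1.0, -1.0)
            cond_trials.append(Trace(clean.t0, clean.dt, v, "pA",
                                     meta={"condition": cond, "trial": k}))
        trials[cond] = cond_trials

    margin = 0.1
    windows = tuple((float(ev - margin), float(ev + spec.artifact_ms + margin))
                    for ev in events)
    truth = {
        "control": {"M": spec.transient.M, "r": spec.transient.r,
                    "ambient": spec.transient.ambient, "g_max": spec.g_max,
                    "leak_offset": spec.leak_offset},
        "block": {"M": spec.transient.M * spec.M_fold, "r": spec.transient.r,
                  "ambient": spec.transient.ambient * spec.ambient_fold,
                  "g_max": spec.g_max * spec.gmax_fold,
                  "leak_offset": spec.leak_offset},
        "folds": {"ambient": spec.ambient_fold, "M": spec.M_fold,
                  "g_max": spec.gmax_fold},
        "noise_sd": spec.noise_sd, "seed": spec.seed,
    }
    return SyntheticRecording(trials=trials, artifact_windows=windows, truth=truth)


#: log-sd of the per-cell parameter draws around the cohort centers
_COHORT_LOG_SD = {"ambient": 0.35, "M": 0.25, "r": 0.2, "g_max": 0.2}


def generate_cohort(n_cells: int, centers: dict | None = None,
                    log_sd: dict | None = None, seed: int = 0,
                    **spec_overrides) -> list[SyntheticCellSpec]:
    """Draw a cohort of cell specs from log-normal population distributions.

    Centers default to the cohort means the control condition reports
    (ambient ~4.7 uM, r ~1.23 um); zero-variance distributions reproduce
    the center spec exactly.  Fully reproducible for a given seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    centers = {**COHORT_CENTERS, **(centers or {})}
    log_sd = {**_COHORT_LOG_SD, **(log_sd or {})}
    rng = np.random.default_rng(seed)
    cells = []
    for k in range(n_cells):
        draw = {name: centers[name] * np.exp(rng.normal(0.0, log_sd.get(name, 0.0)))
                for name in ("ambient", "M", "r", "g_max")}
        leak = rng.normal(-20.0, 5.0)
        cells.append(SyntheticCellSpec(
            transient=TransientParams(M=draw["M"], r=draw["r"], ambient=draw["ambient"]),
            g_max=draw["g_max"], leak_offset=float(leak),
            seed=int(rng.integers(0, 2**31 - 1)),
            **spec_overrides))
    return cells


def generate_spike_response(stimulus_spec: StimulusSpec, onset_gain: float = 0.0,
                            offset_gain: float = 30.0, offset_phase_deg: float = 206.0,
                            baseline_rate: float = 2.0, seed: int = 0,
                            n_sweeps: int = 1, width_deg: float = 30.0) -> np.ndarray:
    """Inhomogeneous-Poisson spike times locked to the modulation cycle.

    The rate (spikes/s) over the modulated segment is ``baseline`` plus a
    wrapped-Gaussian onset component peaking at 90 deg (gain = peak rate
    above baseline) and an offset component peaking at
    ``offset_phase_deg``.  Spikes are drawn by thinning; times are on the
    protocol time base (ms), sweeps concatenated.  Deterministic per seed.
    """
    if onset_gain < 0 or offset_gain < 0 or baseline_rate < 0:
        raise ValueError("rates and gains must be >= 0")
    rng = np.random.default_rng(seed)
    t0 = stimulus_spec.t_mod_start_ms
    dur = stimulus_spec.modulated_s * 1000.0

    def bump(theta, center):
        d = np.deg2rad(theta - center)
        # wrapped Gaussian via the nearest-image approximation
        d = np.arctan2(np.sin(d), np.cos(d))
        return np.exp(-0.5 * (np.rad2deg(d) / width_deg) ** 2)

    def rate_hz(t_ms):
        theta = stimulus_spec.phase_deg(t_ms)
        return (baseline_rate + onset_gain * bump(theta, 90.0)
                + offset_gain * bump(theta, offset_phase_deg))

    lam_max = baseline_rate + onset_gain + offset_gain
    out = []
    for _ in range(n_sweeps):
        if lam_max <= 0:
            continue
        n_cand = rng.poisson(lam_max * dur / 1000.0)
        cand = np.sort(rng.uniform(t0, t0 + dur, n_cand))
        keep = rng.uniform(0.0, lam_max, n_cand) < rate_hz(cand)
        out.append(cand[keep])
    return np.concatenate(out) if out else np.empty(0)
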