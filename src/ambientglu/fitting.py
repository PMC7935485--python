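"""Least-squares fitting of simulated AMPAR currents to recorded traces.

The forward model chains the packages' stages: a stimulus train drives the
point-source diffusion model, the resulting glutamate time course drives
the 13-state receptor scheme (pre-equilibrated at the ambient
concentration, so tonic desensitization is part of the prediction), and
the open-state occupancy yields an ohmic current plus a constant leak
offset.  The recorded trace is trial-averaged, zero-phase low-pass
filtered (1 kHz) and artifact-blanked before fitting; the simulated
current passes through the same filter so both sides see the same
bandwidth.

The estimation protocol mirrors a two-stage design: a control fit frees
{M, r, ambient, g_max, leak_offset}; the transporter-block (EAAT-block)
refit then frees only {ambient, M} (optionally g_max) with everything else
inherited from the paired control fit.  The optimizer is a bounded
derivative-free principal-axis (Powell) search on log-transformed
parameters with jittered restarts; the conductance scale and leak enter
the model linearly and are profiled out by exact linear least squares at
every objective evaluation, which removes the two best-behaved directions
from the nonlinear search without changing the minimum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.signal import butter, filtfilt

from .glutamate import TransientParams, train_concentration
from .kinetics import RateScheme, VoltageParams, equilibrium_occupancy, propagate
from .trace import Trace

__all__ = ["FitSpec", "FitResult", "preprocess_trace", "lowpass",
           "simulate_current", "fit_control", "fit_eaat_block",
           "error_reduction", "PARAM_NAMES"]

PARAM_NAMES = ("M", "r", "ambient", "g_max", "leak_offset")
#: parameters entering the current linearly (profiled out in closed form)
_LINEAR = ("g_max", "leak_offset")
#: positive parameters searched in log space
_LOG = ("M", "r", "ambient")

_DEFAULT_BOUNDS = {
    "M": (1e4, 1e9),          # molecules per event
    "r": (0.2, 5.0),          # um
    "ambient": (1e-3, 100.0), # uM
    "g_max": (0.1, 200.0),    # nS
    "leak_offset": (-500.0, 500.0),  # pA
}
_DEFAULT_INIT = {"M": 2e6, "r": 1.0, "ambient": 2.0, "g_max": 8.0, "leak_offset": 0.0}


@dataclass
class FitSpec:
    """Which parameters are free, their bounds/initials, optimizer settings.

    ``free`` maps a parameter name to ``(initial, lower, upper)``; ``fixed``
    maps the remaining names to values.  Names not listed anywhere get the
    package defaults as fixed values.
    """

    free: dict = field(default_factory=lambda: {
        name: (_DEFAULT_INIT[name], *_DEFAULT_BOUNDS[name]) for name in PARAM_NAMES})
    fixed: dict = field(default_factory=dict)
    alpha: float = 0.21
    D: float = 0.33
    lam: float = 1.55
    maxfev: int = 4000
    xtol: float = 1e-4
    restarts: int = 3
    jitter: float = 0.3      # log-space sd of restart perturbations
    seed: int = 0

    def __post_init__(self):
        for name, (x0, lo, hi) in self.free.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite with lower < upper")
            if not (lo <= x0 <= hi):
                raise ValueError(f"initial value for {name!r} outside bounds")
        for name in self.fixed:
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            if name in self.free:
                raise ValueError(f"parameter {name!r} both free and fixed")

    def value_of(self, name: str) -> float:
        if name in self.fixed:
            return float(self.fixed[name])
        if name in self.free:
            return float(self.free[name][0])
        return _DEFAULT_INIT[name]


@dataclass
class FitResult:
    """Fitted parameters with restart-spread uncertainties and provenance."""

    params: dict                 # all five parameter values
    free_names: tuple
    objective: float             # square norm of residuals over the fit window
    residual: Trace
    condition: str = "control"   # or "eaat-block"
    spread: dict = field(default_factory=dict)   # per-free-param sd across restarts
    converged: bool = True
    seed: int = 0
    restart_objectives: tuple = ()
    control: "FitResult | None" = None

    def __post_init__(self):
        if self.objective < 0:
            raise ValueError("objective must be >= 0")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def lowpass(values: np.ndarray, fs_khz: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (filtfilt)."""
    nyq_hz = fs_khz * 1000.0 / 2.0
    if cutoff_hz >= nyq_hz:
        return np.asarray(values, dtype=float).copy()
    b, a = butter(4, cutoff_hz / nyq_hz)
    return filtfilt(b, a, values)


def preprocess_trace(trace, artifact_windows=(), filter_cutoff: float = 1000.0,
                     n_average: int | None = None) -> Trace:
    """Trial-average, blank stimulation artifacts, low-pass filter.

    ``trace`` may be a single :class:`Trace` or a list of repeated-trial
    traces on an identical time base (averaged sample-wise; ``n_average``
    optionally checks the count).  Artifact windows are (start_ms, stop_ms)
    pairs replaced by linear interpolation *before* filtering so artifact
    energy cannot ring through the filter; the affected samples are marked
    in ``meta['blanked']`` and excluded from fit objectives.
    """
    if isinstance(trace, (list, tuple)):
        traces = list(trace)
        if n_average is not None and len(traces) != n_average:
            raise ValueError(f"expected {n_average} trials, got {len(traces)}")
        base = traces[0]
        for tr in traces[1:]:
            if tr.n != base.n or tr.dt != base.dt or tr.t0 != base.t0:
                raise ValueError("trial traces must share one time base")
        values = np.mean([tr.values for tr in traces], axis=0)
        out = Trace(base.t0, base.dt, values, base.unit, dict(base.meta))
    else:
        out = trace.copy()

    t = out.times
    blanked = np.zeros(out.n, dtype=bool)
    windows = sorted(tuple(w) for w in artifact_windows)
    for k, (w0, w1) in enumerate(windows):
        if w1 <= w0:
            raise ValueError(f"malformed artifact window ({w0}, {w1})")
        if k and w0 < windows[k - 1][1]:
            raise ValueError("overlapping artifact windows")
        if w1 <= t[0] or w0 >= t[-1]:
            raise ValueError(f"artifact window ({w0}, {w1}) outside trace span")
        blanked |= (t >= w0) & (t < w1)
    if blanked.any():
        good = ~blanked
        out.values[blanked] = np.interp(t[blanked], t[good], out.values[good])
    out.values = lowpass(out.values, out.fs_khz, filter_cutoff)
    out.meta["blanked"] = blanked
    out.meta["filter_cutoff_hz"] = filter_cutoff
    return out


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def simulate_current(scheme: RateScheme, transient_params: TransientParams,
                     train, volts: VoltageParams = VoltageParams(),
                     leak_offset: float = 0.0, *, t0: float = 0.0,
                     t_end: float | None = None, fs_khz: float = 5.0,
                     method: str = "grid") -> Trace:
    """Simulated whole-cell AMPAR current (pA) for one stimulus train.

    The receptor pool starts at its equilibrium for the ambient
    concentration.  ``t_end`` defaults to 1000 ms past the last event.
    """
    events = np.asarray(getattr(train, "event_times", train), dtype=float)
    if t_end is None:
        t_end = (events[-1] if events.size else t0) + 1000.0
    tgrid = t0 + np.arange(int(np.round((t_end - t0) * fs_khz)) + 1) / fs_khz
    conc = train_concentration(transient_params, events, tgrid)
    init = equilibrium_occupancy(scheme, transient_params.ambient)
    occ = propagate(scheme, conc, init, method=method)
    cur = scheme.g_max * (occ @ scheme.conductance_weights()) * (volts.v - volts.Erev)
    return Trace(t0, 1.0 / fs_khz, cur + leak_offset, unit="pA",
                 meta={"leak_offset": leak_offset, "ambient": transient_params.ambient})


# ---------------------------------------------------------------------------
# objective machinery
# ---------------------------------------------------------------------------

class _Objective:
    """SSR between the preprocessed data and the filtered forward model.

    The open-state occupancy time course is computed once per nonlinear
    parameter vector; conductance scale and leak (when free) are then
    profiled out by exact linear least squares on the unblanked samples.
    """

    def __init__(self, data: Trace, train, scheme: RateScheme, spec: FitSpec,
                 volts: VoltageParams, fs_fit_khz: float):
        step = max(int(round(data.fs_khz / fs_fit_khz)), 1)
        self.y = data.values[::step]
        self.t = data.times[::step]
        self.dt = data.dt * step
        blanked = data.meta.get("blanked")
        self.mask = ~blanked[::step] if blanked is not None else np.ones_like(self.y, bool)
        self.cutoff = data.meta.get("filter_cutoff_hz", 1000.0)
        self.events = np.asarray(getattr(train, "event_times", train), dtype=float)
        self.scheme = scheme
        self.spec = spec
        self.volts = volts
        self.nl_names = [n for n in spec.free if n not in _LINEAR]
        self.lin_names = [n for n in spec.free if n in _LINEAR]
        self.n_calls = 0

    def _drive(self, values: dict) -> np.ndarray:
        """Filtered per-unit-conductance current for the nonlinear params.

        The drive passes through the same blank-and-filter chain as the
        data: artifact windows are linearly interpolated before filtering,
        so the smoothing the blanks impose near window edges is identical
        on both sides of the residual.
        """
        params = TransientParams(M=values["M"], r=values["r"],
                                 ambient=values["ambient"], alpha=self.spec.alpha,
                                 D=self.spec.D, lam=self.spec.lam)
        conc = train_concentration(params, self.events, self.t)
        init = equilibrium_occupancy(self.scheme, params.ambient)
        occ = propagate(self.scheme, conc, init, method="grid")
        drive = (occ @ self.scheme.conductance_weights()) * (self.volts.v - self.volts.Erev)
        if not self.mask.all():
            drive = drive.copy()
            drive[~self.mask] = np.interp(self.t[~self.mask], self.t[self.mask],
                                          drive[self.mask])
        return lowpass(drive, 1.0 / self.dt, self.cutoff)

    def __call__(self, z: np.ndarray) -> float:
        return self.eval_full(z)[0]

    def eval_full(self, z: np.ndarray):
        self.n_calls += 1
        values = {n: self.spec.value_of(n) for n in PARAM_NAMES}
        for n in self.spec.fixed:
            values[n] = float(self.spec.fixed[n])
        for n, zi in zip(self.nl_names, z):
            values[n] = float(np.exp(zi)) if n in _LOG else float(zi)
        drive = self._drive(values)
        y, m = self.y, self.mask
        # profile the linear parameters on the unblanked samples
        cols = []
        if "g_max" in self.lin_names:
            cols.append(drive[m])
        if "leak_offset" in self.lin_names:
            cols.append(np.ones(m.sum()))
        if cols:
            A = np.column_stack(cols)
            coef, *_ = np.linalg.lstsq(A, y[m], rcond=None)
            i = 0
            for name in ("g_max", "leak_offset"):
                if name in self.lin_names:
                    lo, hi = self.spec.free[name][1:]
                    values[name] = float(np.clip(coef[i], lo, hi))
                    i += 1
        model = values["g_max"] * drive + values["leak_offset"]
        resid = y - model
        ssr = float(np.sum(resid[m] ** 2))
        return ssr, values, resid


def _run_fit(objective: _Objective, spec: FitSpec, condition: str,
             control: FitResult | None = None) -> FitResult:
    rng = np.random.default_rng(spec.seed)
    z0, lo, hi = [], [], []
    for n in objective.nl_names:
        x0, l, h = spec.free[n]
        if n in _LOG:
            z0.append(np.log(x0)); lo.append(np.log(l)); hi.append(np.log(h))
        else:
            z0.append(x0); lo.append(l); hi.append(h)
    z0, lo, hi = map(np.asarray, (z0, lo, hi))

    best = None
    solutions, objs = [], []
    converged = False
    for k in range(max(spec.restarts, 1)):
        zk = z0 if k == 0 else np.clip(z0 + rng.normal(0, spec.jitter, z0.size), lo, hi)
        if z0.size:
            res = minimize(objective, zk, method="Powell",
                           bounds=list(zip(lo, hi)),
                           options={"maxfev": spec.maxfev, "xtol": spec.xtol,
                                    "ftol": spec.xtol})
            converged = converged or bool(res.success)
            zbest, fbest = res.x, float(res.fun)
        else:  # purely linear problem
            zbest, fbest = zk, objective(zk)
            converged = True
        solutions.append(zbest)
        objs.append(fbest)
        if best is None or fbest < best[1]:
            best = (zbest, fbest)

    ssr, values, resid = objective.eval_full(best[0])
    # restart spread on the natural scale, free parameters only
    spread = {}
    sols = np.atleast_2d(np.asarray(solutions))
    for j, n in enumerate(objective.nl_names):
        col = np.exp(sols[:, j]) if n in _LOG else sols[:, j]
        spread[n] = float(np.std(col))
    return FitResult(
        params=values, free_names=tuple(spec.free), objective=ssr,
        residual=Trace(objective.t[0], objective.dt, resid, unit="pA",
                       meta={"mask": objective.mask}),
        condition=condition, spread=spread, converged=converged,
        seed=spec.seed, restart_objectives=tuple(objs), control=control,
    )


def fit_control(data: Trace, train, scheme: RateScheme, spec: FitSpec | None = None,
                volts: VoltageParams = VoltageParams(),
                fs_fit_khz: float = 10.0) -> FitResult:
    """Full fit of the forward model to a preprocessed control trace.

    Free parameters default to {M, r, ambient, g_max, leak_offset}.
    Multi-restart, deterministic for a given ``spec.seed``; a fit that
    never reports optimizer success is returned flagged
    (``converged=False``), not raised.
    """
    spec = spec if spec is not None else FitSpec()
    obj = _Objective(data, train, scheme, spec, volts, fs_fit_khz)
    return _run_fit(obj, spec, "control")


def fit_eaat_block(data: Trace, train, scheme: RateScheme, control_fit: FitResult,
                   allow_gmax: bool = False, spec: FitSpec | None = None,
                   volts: VoltageParams = VoltageParams(),
                   fs_fit_khz: float = 10.0) -> FitResult:
    """Refit a transporter-block trace varying only ambient and M.

    All other parameters are inherited frozen from the paired control fit;
    with ``allow_gmax`` the conductance scale is freed as well (the
    spillover-to-extra-receptors case).
    """
    if control_fit is None:
        raise ValueError("fit_eaat_block requires the paired control FitResult")
    c = control_fit.params
    free = {
        "ambient": (c["ambient"], *_DEFAULT_BOUNDS["ambient"]),
        "M": (c["M"], *_DEFAULT_BOUNDS["M"]),
    }
    if allow_gmax:
        free["g_max"] = (c["g_max"], *_DEFAULT_BOUNDS["g_max"])
    fixed = {n: c[n] for n in PARAM_NAMES if n not in free}
    base = spec if spec is not None else FitSpec()
    spec = dataclasses.replace(base, free=free, fixed=fixed)
    obj = _Objective(data, train, scheme, spec, volts, fs_fit_khz)
    return _run_fit(obj, spec, "eaat-block", control=control_fit)


def error_reduction(with_ambient: FitResult, without_ambient: FitResult) -> float:
    """Percent reduction of the square norm from adding the ambient
    parameter: 100 * (1 - obj_with / obj_without)."""
    if without_ambient.objective == 0:
        raise ZeroDivisionError("reference fit has zero objective")
    return 100.0 * (1.0 - with_ambient.objective / without_ambient.objective)
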