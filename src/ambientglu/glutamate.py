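"""Glutamate concentration at the receptors: 3D point-source diffusion.

A single release event deposits M molecules at a point in the extracellular
space; the concentration a distance r away follows the instantaneous
point-source solution of the diffusion equation, corrected for brain tissue
by the extracellular volume fraction alpha (released transmitter is
confined to a fraction of the total volume) and tortuosity lambda (the
effective diffusion coefficient is D/lambda^2):

    C(r, tau) = (M / alpha) * (4 pi D_eff tau)^(-3/2) * exp(-r^2 / (4 D_eff tau))

with tau the time since release.  A flat ambient concentration is added as
a floor — the standing extracellular glutamate that persists between
release events.  Trains superpose linearly (no presynaptic depression),
with the ambient floor added exactly once.

Units: distance um, time ms, D um^2/ms, concentration uM, M molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import Trace

__all__ = ["TransientParams", "effective_diffusion", "transient",
           "peak_time", "train_concentration"]

# mol/um^3 -> uM: 1 mol/um^3 = 1e15 mol/L = 1e21 uM; divided by Avogadro
# to convert molecules to moles: 1e21 / 6.02214076e23 = 1 / 602.214076
_MOLECULES_TO_UM_UM3 = 1.0 / 602.214076


@dataclass(frozen=True)
class TransientParams:
    """Parameters of the glutamate field at one synapse.

    M : molecules released per event (converted to moles internally)
    r : um, distance from release site to the receptors
    alpha : extracellular volume fraction (0.21)
    D : um^2/ms, free diffusion coefficient of glutamate (0.33)
    lam : tortuosity (1.55); effective diffusion coefficient is D/lam^2
    ambient : uM, standing glutamate concentration
    """

    M: float
    r: float
    alpha: float = 0.21
    D: float = 0.33
    lam: float = 1.55
    ambient: float = 0.0

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("release-to-receptor distance r must be > 0")
        if self.M < 0 or self.alpha <= 0 or self.D <= 0 or self.lam <= 0:
            raise ValueError("M must be >= 0; alpha, D, lam must be > 0")
        if self.ambient < 0:
            raise ValueError("ambient concentration must be >= 0")


def effective_diffusion(D: float, lam: float) -> float:
    """Tortuosity-corrected diffusion coefficient D/lambda^2 (um^2/ms)."""
    if lam <= 0:
        raise ValueError("tortuosity must be > 0")
    return D / lam**2


def transient(params: TransientParams, t, t0: float = 0.0):
    """Concentration (uM) at the receptors from one event at time t0.

    For t <= t0 the concentration is the ambient floor.  Accepts scalar or
    array times (ms).
    """
    t = np.asarray(t, dtype=float)
    tau = t - t0
    deff = effective_diffusion(params.D, params.lam)
    out = np.full(tau.shape, params.ambient, dtype=float)
    pos = tau > 0
    taup = tau[pos]
    amp = params.M * _MOLECULES_TO_UM_UM3 / (8.0 * params.alpha * (np.pi * deff * taup) ** 1.5)
    out[pos] += amp * np.exp(-params.r**2 / (4.0 * deff * taup))
    if out.ndim == 0:
        return float(out)
    return out


def peak_time(params: TransientParams) -> float:
    """Time after release at which the transient peaks: r^2 / (6 D_eff) ms."""
    return params.r**2 / (6.0 * effective_diffusion(params.D, params.lam))


def train_concentration(params: TransientParams, event_times, tgrid) -> Trace:
    """Linear superposition of per-event transients over a stimulus train.

    ``event_times`` are sorted event times in ms (a :class:`~ambientglu.
    stimulus.StimulusTrain` or a plain sequence); every event releases the
    same M at the same r, and the ambient floor enters once.
    """
    events = np.asarray(getattr(event_times, "event_times", event_times), dtype=float)
    if events.size > 1 and np.any(np.diff(events) <= 0):
        raise ValueError("event times must be strictly increasing")
    tgrid = np.asarray(tgrid, dtype=float)
    dt = float(tgrid[1] - tgrid[0]) if tgrid.size > 1 else 1.0
    c = np.full(tgrid.shape, params.ambient, dtype=float)
    for t0 in events:
        c += transient(params, tgrid, t0) - params.ambient
    return Trace(float(tgrid[0]), dt, c, unit="uM")
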