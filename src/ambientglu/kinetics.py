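"""Continuous-time Markov model of the UBC AMPA receptor.

The receptor is described by a 13-state kinetic scheme: five closed states
``C0..C4`` representing occupation of 0-4 glutamate binding sites, and one
open (``O1..O4``) and one desensitized (``D1..D4``) state branching off each
liganded closed state.  The only ligand-dependent steps are the binding
transitions ``C_i -> C_{i+1}``, whose pseudo-first-order rate is the rate
constant (per ms per uM) times the free glutamate concentration.

The scheme is held in a :class:`RateScheme` and simulated through its
generator (Q) matrix: occupancy evolves as ``dp/dt = A(glu) p`` where the
off-diagonal entry ``A[j, i]`` is the i->j rate and each column sums to
zero.  Because the connectivity is a tree (a binding chain with O/D leaves)
the stationary distribution is unique for any concentration and is obtained
from the null space of ``A``.

Macroscopic current follows the ohmic form ``I = g * (v - Erev)`` with
``g = g_max * sum_k w_k P(O_k)``; the defaults ``v = -70 mV``,
``Erev = 0 mV`` correspond to a voltage-clamped UBC.

Units throughout: time ms, concentration uM, rates /ms or /ms/uM,
conductance nS, voltage mV, current pA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from scipy.linalg import expm, null_space
from scipy.integrate import solve_ivp

from .trace import Trace

__all__ = [
    "N_STATES", "STATE_NAMES", "RateScheme", "VoltageParams", "OccupancyState",
    "SchemeValidationError", "load_rate_scheme", "save_rate_scheme",
    "default_scheme", "scale_rates_q10", "generator_matrix",
    "equilibrium_occupancy", "propagate", "current", "dose_response",
    "DoseResponse",
]

N_STATES = 13
STATE_NAMES = ("C0", "C1", "C2", "C3", "C4",
               "O1", "O2", "O3", "O4",
               "D1", "D2", "D3", "D4")
_OPEN_STATES = ("O1", "O2", "O3", "O4")

#: the allowed edges of the scheme, as unordered pairs
_ALLOWED_EDGES = frozenset(
    [frozenset((f"C{i}", f"C{i+1}")) for i in range(4)]
    + [frozenset((f"C{k}", f"O{k}")) for k in range(1, 5)]
    + [frozenset((f"C{k}", f"D{k}")) for k in range(1, 5)]
)
_BINDING_EDGES = frozenset(frozenset((f"C{i}", f"C{i+1}")) for i in range(4))


class SchemeValidationError(ValueError):
    """Raised when a rate table violates the 13-state scheme contract."""


@dataclass(frozen=True)
class VoltageParams:
    """Holding and reversal potentials (mV) for the ohmic current."""
    v: float = -70.0
    Erev: float = 0.0


@dataclass(frozen=True)
class OccupancyState:
    """State-occupancy probabilities at one instant."""
    probabilities: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.shape != (N_STATES,):
            raise ValueError(f"expected {N_STATES} probabilities, got {p.shape}")
        if np.any(p < -1e-8) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("occupancy probabilities must be >= 0 and sum to 1")

    def __getitem__(self, name: str) -> float:
        return float(self.probabilities[STATE_NAMES.index(name)])


@dataclass(frozen=True)
class RateScheme:
    """The 13-state AMPAR scheme: transitions, conductances, temperature.

    ``transitions`` is a tuple of ``(from_state, to_state, rate,
    ligand_order)`` rows.  ``ligand_order`` is 1 only on binding steps
    ``C_i -> C_{i+1}``, whose rate is per ms per uM; all other rates are
    per ms.  Statistical factors of the four identical binding sites are
    written out in the table, they are not implied.
    """

    transitions: tuple
    open_conductance: dict = field(default_factory=lambda: {s: 1.0 for s in _OPEN_STATES})
    g_max: float = 10.0
    T_ref: float = 23.0
    Q10: float = 2.4
    name: str = "ubc-ampar"

    def __post_init__(self):
        object.__setattr__(self, "transitions", tuple(tuple(t) for t in self.transitions))
        _validate(self)

    # -- derived structure, computed lazily and cached on the instance ----
    def _matrices(self):
        key = "_cached_matrices"
        cached = self.__dict__.get(key)
        if cached is None:
            a0 = np.zeros((N_STATES, N_STATES))
            a1 = np.zeros((N_STATES, N_STATES))
            for src, dst, rate, order in self.transitions:
                i, j = STATE_NAMES.index(src), STATE_NAMES.index(dst)
                tgt = a1 if order == 1 else a0
                tgt[j, i] += rate
                tgt[i, i] -= rate
            cached = (a0, a1)
            self.__dict__[key] = cached
        return cached

    def conductance_weights(self) -> np.ndarray:
        w = np.zeros(N_STATES)
        for s, g in self.open_conductance.items():
            w[STATE_NAMES.index(s)] = g
        return w


def _validate(scheme: RateScheme) -> None:
    seen = set()
    for row in scheme.transitions:
        if len(row) != 4:
            raise SchemeValidationError(f"malformed transition row {row!r}")
        src, dst, rate, order = row
        for s in (src, dst):
            if s not in STATE_NAMES:
                raise SchemeValidationError(f"unknown state {s!r} in row {row!r}")
        if rate < 0:
            raise SchemeValidationError(f"negative rate in row {row!r}")
        if order not in (0, 1):
            raise SchemeValidationError(f"ligand_order must be 0 or 1 in row {row!r}")
        edge = frozenset((src, dst))
        if edge not in _ALLOWED_EDGES:
            raise SchemeValidationError(
                f"transition {src}->{dst} is outside the binding-chain/O/D topology")
        if order == 1 and not (edge in _BINDING_EDGES and src < dst):
            raise SchemeValidationError(
                f"ligand_order 1 only allowed on binding steps C_i->C_{{i+1}}: row {row!r}")
        seen.add((src, dst))
    # every edge must be present in both directions with a positive rate
    for edge in _ALLOWED_EDGES:
        a, b = sorted(edge)
        if (a, b) not in seen or (b, a) not in seen:
            raise SchemeValidationError(f"edge {a}<->{b} missing; scheme would be disconnected")
    for s in scheme.open_conductance:
        if s not in _OPEN_STATES:
            raise SchemeValidationError(f"conductance weight on non-open state {s!r}")
    if scheme.g_max < 0 or scheme.Q10 <= 0:
        raise SchemeValidationError("g_max must be >= 0 and Q10 > 0")


# ---------------------------------------------------------------------------
# rate-table file format (YAML): header block plus one row per transition
# ---------------------------------------------------------------------------

def load_rate_scheme(path) -> RateScheme:
    """Load and validate a rate-table file.

    The table is YAML with keys ``T_ref_C``, ``Q10``, ``g_max_nS``,
    ``open_conductance`` and a ``transitions`` list of
    ``{from, to, rate, ligand_order}`` rows.  Rates are /ms (/ms/uM on
    binding steps).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        rows = tuple((r["from"], r["to"], float(r["rate"]), int(r["ligand_order"]))
                     for r in doc["transitions"])
        scheme = RateScheme(
            transitions=rows,
            open_conductance={k: float(v) for k, v in doc["open_conductance"].items()},
            g_max=float(doc["g_max_nS"]),
            T_ref=float(doc["T_ref_C"]),
            Q10=float(doc["Q10"]),
            name=str(doc.get("name", "rate-table")),
        )
    except KeyError as exc:
        raise SchemeValidationError(f"{path}: missing key {exc}") from None
    return scheme


def save_rate_scheme(scheme: RateScheme, path) -> None:
    """Write a scheme back to the YAML rate-table format (lossless)."""
    doc = {
        "name": scheme.name,
        "units": {"time": "ms", "concentration": "uM",
                  "conductance": "nS", "voltage": "mV"},
        "T_ref_C": scheme.T_ref,
        "Q10": scheme.Q10,
        "g_max_nS": scheme.g_max,
        "open_conductance": dict(scheme.open_conductance),
        "transitions": [
            {"from": s, "to": d, "rate": float(r), "ligand_order": int(o)}
            for s, d, r, o in scheme.transitions
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_scheme() -> RateScheme:
    """The calibrated rate table shipped with the package.

    Calibrated (``scripts/calibrate_rate_table.py``) so that the
    equilibrium dose-response is bell-shaped with its peak at 32 uM, the
    steady-state current at 1 mM is well below the peak value, 54.2% of
    receptors are unbound at 5 uM glutamate, deactivation after transmitter
    removal takes a few ms, and recovery from the deep (3-4 bound)
    desensitized states takes on the order of 100 ms at room temperature.
    """
    ref = resources.files("ambientglu") / "data" / "default_rates.yaml"
    with resources.as_file(ref) as p:
        return load_rate_scheme(p)


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def scale_rates_q10(scheme: RateScheme, T_target: float) -> RateScheme:
    """Rescale every rate by ``Q10 ** ((T_target - T_ref) / 10)``.

    A single multiplicative factor applied to all transitions speeds every
    relaxation without moving any equilibrium: occupancies and the whole
    dose-response curve are unchanged.
    """
    factor = scheme.Q10 ** ((T_target - scheme.T_ref) / 10.0)
    rows = tuple((s, d, r * factor, o) for s, d, r, o in scheme.transitions)
    return replace(scheme, transitions=rows, T_ref=T_target)


def generator_matrix(scheme: RateScheme, glu: float) -> np.ndarray:
    """The Q matrix at a fixed glutamate concentration (uM).

    ``A[j, i]`` is the i->j rate; binding rates are multiplied by ``glu``;
    columns sum to zero.
    """
    if glu < 0:
        raise ValueError("glutamate concentration must be >= 0")
    a0, a1 = scheme._matrices()
    return a0 + glu * a1


def equilibrium_occupancy(scheme: RateScheme, glu: float) -> OccupancyState:
    """Stationary occupancy at a fixed concentration (null space of Q)."""
    a = generator_matrix(scheme, glu)
    ns = null_space(a, rcond=1e-10)
    if ns.shape[1] != 1:
        raise SchemeValidationError(
            f"stationary distribution not unique ({ns.shape[1]} null vectors); "
            "scheme is disconnected or degenerate")
    p = ns[:, 0]
    p = p * np.sign(p.sum())
    p = np.clip(p, 0.0, None)
    return OccupancyState(p / p.sum())


class IntegrationError(RuntimeError):
    """Raised when occupancy propagation violates its probability contract."""


def propagate(scheme: RateScheme, glu: Trace, initial: OccupancyState | None = None,
              method: str = "expm", rtol: float = 1e-8, atol: float = 1e-10,
              prob_tol: float = 1e-6) -> np.ndarray:
    """Integrate ``dp/dt = A(glu(t)) p`` along a concentration trace.

    Parameters
    ----------
    glu : Trace
        Nonnegative glutamate concentration, uM, uniformly sampled.
    initial : OccupancyState, optional
        Defaults to the equilibrium at the first concentration sample.
    method : {"expm", "ode", "grid"}
        ``expm``: per-sample matrix exponential treating the concentration
        as piecewise-constant over each interval (left sample value); the
        reference path.  ``ode``: adaptive stiff solver (LSODA) on the
        linearly interpolated concentration.  ``grid``: the fast path used
        inside fitting -- propagators interpolated from a precomputed
        log-concentration grid (see :class:`PropagatorGrid`).

    Returns
    -------
    ndarray, shape (n, 13)
        Occupancy at each sample of ``glu``.
    """
    c = np.asarray(glu.values, dtype=float)
    if np.any(c < 0):
        raise ValueError("glutamate concentrations must be >= 0")
    if initial is None:
        initial = equilibrium_occupancy(scheme, float(c[0]))
    p0 = initial.probabilities
    if method == "expm":
        out = _propagate_expm(scheme, c, glu.dt, p0)
    elif method == "ode":
        out = _propagate_ode(scheme, c, glu.dt, p0, rtol, atol)
    elif method == "grid":
        grid = PropagatorGrid.for_scheme(scheme, glu.dt)
        out = grid.propagate(c, p0)
    else:
        raise ValueError(f"unknown method {method!r}")
    sums = out.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > prob_tol) or np.any(out < -prob_tol):
        raise IntegrationError(
            f"probability contract violated: max |sum-1| = {np.abs(sums - 1).max():.3g}, "
            f"min p = {out.min():.3g}")
    return out


def _propagate_expm(scheme, c, dt, p0):
    a0, a1 = scheme._matrices()
    n = c.size
    out = np.empty((n, N_STATES))
    out[0] = p = p0.copy()
    # cache the propagator while the concentration does not change
    last_c, last_m = None, None
    for i in range(n - 1):
        ci = c[i]
        if ci != last_c:
            last_m = expm((a0 + ci * a1) * dt)
            last_c = ci
        p = last_m @ p
        out[i + 1] = p
    return out


def _propagate_ode(scheme, c, dt, p0, rtol, atol):
    a0, a1 = scheme._matrices()
    t = dt * np.arange(c.size)
    n = c.size

    def rhs(ti, p):
        # same piecewise-constant (left-sample) concentration as the expm
        # path, so the two integrators solve the identical problem
        ci = c[min(int(ti / dt), n - 1)]
        return (a0 + ci * a1) @ p

    sol = solve_ivp(rhs, (t[0], t[-1]), p0, method="LSODA", t_eval=t,
                    rtol=rtol, atol=atol, max_step=dt)
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    return sol.y.T


class PropagatorGrid:
    """Per-sample propagators interpolated on a log-concentration grid.

    ``expm(A(c) * dt)`` is precomputed on a dense logarithmic grid of
    concentrations; stepping a trace then costs one 13x13 matrix-vector
    product per sample, with the propagator linearly interpolated (in log
    concentration) between the two bracketing grid entries.  The grid
    depends only on the scheme and the step size, so a fit re-uses one grid
    across all objective evaluations.  Concentrations outside the grid are
    clipped to its ends; the default range (1e-3 .. 1e5 uM) brackets
    anything the diffusion model produces.
    """

    _cache: dict = {}

    def __init__(self, scheme: RateScheme, dt: float,
                 c_min: float = 1e-3, c_max: float = 1e5, n_grid: int = 512):
        a0, a1 = scheme._matrices()
        self.dt = dt
        self.log_c = np.linspace(math.log(c_min), math.log(c_max), n_grid)
        self.props = np.empty((n_grid, N_STATES, N_STATES))
        for k, lc in enumerate(self.log_c):
            self.props[k] = expm((a0 + math.exp(lc) * a1) * dt)
        # a zero-concentration propagator handled separately (log undefined)
        self.prop_zero = expm(a0 * dt)
        self.c_min, self.c_max = c_min, c_max

    @classmethod
    def for_scheme(cls, scheme: RateScheme, dt: float) -> "PropagatorGrid":
        key = (id(scheme), round(dt, 12))
        grid = cls._cache.get(key)
        if grid is None:
            grid = cls(scheme, dt)
            cls._cache[key] = grid
        return grid

    def propagate(self, c: np.ndarray, p0: np.ndarray) -> np.ndarray:
        from ._stepper import step_chain  # deferred: numba jit compile
        steps = c[:-1]
        lc = np.log(np.clip(steps, self.c_min, self.c_max))
        x = (lc - self.log_c[0]) / (self.log_c[1] - self.log_c[0])
        idx = np.clip(x.astype(np.int64), 0, self.log_c.size - 2)
        w = np.clip(x - idx, 0.0, 1.0)
        zero = steps == 0.0  # exact zero bypasses the log grid
        return step_chain(self.props, idx, w, p0, zero, self.prop_zero)


def current(occupancy, scheme: RateScheme, volts: VoltageParams = VoltageParams()) -> float | np.ndarray:
    """Ohmic AMPAR current, pA: ``g_max * sum_k w_k P(O_k) * (v - Erev)``.

    ``occupancy`` may be a single :class:`OccupancyState` (returns a float)
    or an (n, 13) array of occupancies (returns an array).
    """
    w = scheme.conductance_weights()
    if isinstance(occupancy, OccupancyState):
        g = scheme.g_max * float(occupancy.probabilities @ w)
    else:
        g = scheme.g_max * np.asarray(occupancy) @ w
    return g * (volts.v - volts.Erev)


@dataclass(frozen=True)
class DoseResponse:
    """Equilibrium current as a function of glutamate concentration."""
    concentrations: np.ndarray
    currents: np.ndarray
    peak_concentration: float  # argmax of |current|


def dose_response(scheme: RateScheme, conc_grid, volts: VoltageParams = VoltageParams()) -> DoseResponse:
    """Steady-state current over a sorted grid of concentrations (uM)."""
    grid = np.asarray(conc_grid, dtype=float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("concentration grid must be positive and strictly increasing")
    cur = np.array([current(equilibrium_occupancy(scheme, ci), scheme, volts)
                    for ci in grid])
    peak = float(grid[int(np.argmax(np.abs(cur)))])
    return DoseResponse(grid, cur, peak)
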