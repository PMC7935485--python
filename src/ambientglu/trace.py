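"""Uniformly sampled time-series container and its plain-text round-trip.

Every stage of the pipeline (glutamate concentration, receptor occupancy,
membrane current) exchanges data as a :class:`Trace`: a uniformly sampled
series with an explicit unit label.  On disk a trace is two-column
tab-delimited text whose first line is a ``#``-prefixed header naming the
column units, e.g. ``# time_ms\tcurrent_pA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace", "read_trace", "write_trace", "TraceFormatError"]


class TraceFormatError(ValueError):
    """Raised when a trace file is malformed or its unit header is missing."""


@dataclass
class Trace:
    """A uniformly sampled time series.

    Parameters
    ----------
    t0 : float
        Time of the first sample, in ms.
    dt : float
        Sampling interval, in ms.
    values : ndarray
        Sample values.
    unit : str
        Unit label for the values column (``pA``, ``uM``, ``prob`` ...).
    meta : dict
        Free-form metadata (condition tags, blanked-sample masks, seeds).
    """

    t0: float
    dt: float
    values: np.ndarray
    unit: str = "pA"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if not (self.dt > 0):
            raise ValueError("sampling interval must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def fs_khz(self) -> float:
        """Sampling rate in kHz (samples per ms)."""
        return 1.0 / self.dt

    def copy(self) -> "Trace":
        return Trace(self.t0, self.dt, self.values.copy(), self.unit, dict(self.meta))

    def slice(self, t_start: float, t_stop: float) -> "Trace":
        """Return the sub-trace with t_start <= t < t_stop (ms)."""
        i0 = int(np.ceil((t_start - self.t0) / self.dt - 1e-9))
        i1 = int(np.ceil((t_stop - self.t0) / self.dt - 1e-9))
        i0, i1 = max(i0, 0), min(max(i1, 0), self.n)
        return Trace(self.t0 + i0 * self.dt, self.dt, self.values[i0:i1].copy(),
                     self.unit, dict(self.meta))


def write_trace(trace: Trace, path) -> None:
    """Write a trace as two-column tab-delimited text with a unit header."""
    t = trace.times
    with open(path, "w") as fh:
        fh.write(f"# time_ms\t{trace.unit}\n")
        for ti, vi in zip(t, trace.values):
            fh.write(f"{ti:.6f}\t{vi:.9g}\n")


def read_trace(path, expect_unit: str | None = None) -> Trace:
    """Read a two-column trace file written by :func:`write_trace`.

    Raises
    ------
    TraceFormatError
        If the unit header is missing, the unit does not match
        ``expect_unit``, a line does not split into two fields, or the time
        base is not uniform.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or not lines[0].startswith("#"):
        raise TraceFormatError(f"{path}: missing '# time_ms\\t<unit>' header line")
    header = lines[0][1:].split()
    if len(header) != 2 or header[0] != "time_ms":
        raise TraceFormatError(f"{path}: malformed unit header {lines[0]!r}")
    unit = header[1]
    if expect_unit is not None and unit != expect_unit:
        raise TraceFormatError(f"{path}: unit {unit!r}, expected {expect_unit!r}")
    t, v = [], []
    for k, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TraceFormatError(f"{path}: line {k} is not two tab-separated fields")
        try:
            t.append(float(parts[0]))
            v.append(float(parts[1]))
        except ValueError as exc:
            raise TraceFormatError(f"{path}: line {k}: {exc}") from None
    t = np.asarray(t)
    v = np.asarray(v)
    if t.size == 0:
        raise TraceFormatError(f"{path}: no samples")
    if t.size == 1:
        return Trace(t[0], 1.0, v, unit)
    dts = np.diff(t)
    dt = float(np.median(dts))
    if not np.allclose(dts, dt, rtol=0, atol=max(1e-6, 1e-6 * dt)):
        raise TraceFormatError(f"{path}: non-uniform time base")
    return Trace(float(t[0]), dt, v, unit)
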