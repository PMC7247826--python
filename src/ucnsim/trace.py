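"""Sampled simulation traces and their CSV round-trip.

A :class:`Trace` holds equal-length columns ``t, u, v_mem, v_out,
conducting`` sampled on a uniform grid plus the exact switching times, each
event time appearing twice (left/right limits, pre- and post-transition
discrete state).

CSV format: header ``t,u,v_mem,v_out,conducting``; floats serialized with
``%.17g`` (which round-trips IEEE doubles bit-exactly), ``conducting`` as
0/1.  Re-writing a file that was read back therefore reproduces it byte for
byte.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import TraceIOError

__all__ = ["Trace", "write_trace", "read_trace"]

COLUMNS = ("t", "u", "v_mem", "v_out", "conducting")


@dataclass
class Trace:
    """Time series of a hybrid simulation (SI units)."""

    t: np.ndarray
    u: np.ndarray
    v_mem: np.ndarray
    v_out: np.ndarray
    conducting: np.ndarray
    dt_nominal: float
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v_mem = np.asarray(self.v_mem, dtype=float)
        self.v_out = np.asarray(self.v_out, dtype=float)
        self.conducting = np.asarray(self.conducting, dtype=bool)
        n = len(self.t)
        for name in ("u", "v_mem", "v_out", "conducting"):
            if len(getattr(self, name)) != n:
                raise TraceIOError(f"trace column {name!r} has length "
                                   f"{len(getattr(self, name))}, expected {n}")
        if np.any(np.diff(self.t) < 0):
            raise TraceIOError("trace times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def t_end(self) -> float:
        return float(self.t[-1]) if len(self.t) else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "u": self.u, "v_mem": self.v_mem,
             "v_out": self.v_out, "conducting": self.conducting.astype(int)}
        )

    def equals(self, other: "Trace") -> bool:
        """Column-wise exact equality of the samples (metadata excluded)."""
        return (
            len(self) == len(other)
            and bool(np.array_equal(self.t, other.t))
            and bool(np.array_equal(self.u, other.u))
            and bool(np.array_equal(self.v_mem, other.v_mem))
            and bool(np.array_equal(self.v_out, other.v_out))
            and bool(np.array_equal(self.conducting, other.conducting))
        )


def write_trace(trace: Trace, path) -> None:
    """Write a trace to CSV with bit-exact float text representation."""
    buf = io.StringIO()
    buf.write(",".join(COLUMNS) + "\n")
    for i in range(len(trace)):
        buf.write(
            f"{trace.t[i]:.17g},{trace.u[i]:.17g},{trace.v_mem[i]:.17g},"
            f"{trace.v_out[i]:.17g},{int(trace.conducting[i])}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_trace(path) -> Trace:
    """Read a trace CSV written by :func:`write_trace`.

    Raises
    ------
    TraceIOError
        On an empty file or a malformed header, naming the missing column.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise TraceIOError(f"empty trace file: {path}") from exc
    for col in COLUMNS:
        if col not in df.columns:
            raise TraceIOError(f"trace file {path} is missing column {col!r}")
    t = df["t"].to_numpy(dtype=float)
    diffs = np.diff(t)
    positive = diffs[diffs > 0]
    dt_nominal = float(np.median(positive)) if len(positive) else 0.0
    return Trace(
        t=t,
        u=df["u"].to_numpy(dtype=float),
        v_mem=df["v_mem"].to_numpy(dtype=float),
        v_out=df["v_out"].to_numpy(dtype=float),
        conducting=df["conducting"].to_numpy(dtype=float).astype(bool),
        dt_nominal=dt_nominal,
    )
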