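"""Deterministic input-current waveforms driving the neuron circuits.

All stimuli follow a current-source convention: ``u(t)`` is the current
[A] injected at the circuit input node, zero before ``t_on``.  Waveforms are
piecewise constant or piecewise linear; the breakpoints are exposed so the
integrator can split the time axis there and never step across a
discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["Stimulus", "make_stimulus", "STIMULUS_KINDS"]

_REQUIRED: dict[str, tuple[str, ...]] = {
    "step": ("t_on", "amplitude"),
    "pulse_train": ("t_on", "amplitude", "width", "period", "count"),
    "paired_pulse": ("t_on", "amplitude", "width", "gap"),
    "ramp": ("t_on", "slope", "amplitude"),
    "ramp_then_step": ("t_on", "slope", "amplitude", "gap", "width"),
    "negative_step": ("t_on", "amplitude"),
    "negative_pulse": ("t_on", "amplitude", "width"),
}

STIMULUS_KINDS = tuple(_REQUIRED)


@dataclass(frozen=True)
class Stimulus:
    """A deterministic input waveform ``u(t)`` with declared kind and parameters."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)

    def __call__(self, t):
        """Evaluate u(t) [A]; works on scalars and numpy arrays."""
        p = self.params
        t = np.asarray(t, dtype=float)
        k = self.kind
        if k == "step" or k == "negative_step":
            u = np.where(t >= p["t_on"], p["amplitude"], 0.0)
        elif k == "pulse_train":
            rel = t - p["t_on"]
            idx = np.floor_divide(rel, p["period"])
            inside = (rel >= 0) & (idx < p["count"]) & (rel - idx * p["period"] < p["width"])
            u = np.where(inside, p["amplitude"], 0.0)
        elif k == "paired_pulse":
            t0, w, g, a = p["t_on"], p["width"], p["gap"], p["amplitude"]
            first = (t >= t0) & (t < t0 + w)
            second = (t >= t0 + w + g) & (t < t0 + 2 * w + g)
            u = np.where(first | second, a, 0.0)
        elif k == "ramp":
            u = np.clip(p["slope"] * (t - p["t_on"]), 0.0, p["amplitude"])
        elif k == "ramp_then_step":
            t0, s, a, g, w = p["t_on"], p["slope"], p["amplitude"], p["gap"], p["width"]
            t1 = t0 + a / s  # end of ramp, input drops back to zero
            ramp = np.where((t >= t0) & (t < t1), s * (t - t0), 0.0)
            pulse = np.where((t >= t1 + g) & (t < t1 + g + w), a, 0.0)
            u = ramp + pulse
        elif k == "negative_pulse":
            t0, w, a = p["t_on"], p["width"], p["amplitude"]
            u = np.where((t >= t0) & (t < t0 + w), a, 0.0)
        else:  # pragma: no cover - guarded by make_stimulus
            raise ConfigurationError(f"unknown stimulus kind {k!r}")
        return float(u) if u.ndim == 0 else u

    def breakpoints(self) -> list[float]:
        """Times where u(t) or its slope is discontinuous (integration split points)."""
        p = self.params
        k = self.kind
        if k in ("step", "negative_step"):
            return [p["t_on"]]
        if k == "pulse_train":
            bps = []
            for i in range(int(p["count"])):
                start = p["t_on"] + i * p["period"]
                bps += [start, start + p["width"]]
            return bps
        if k == "paired_pulse":
            t0, w, g = p["t_on"], p["width"], p["gap"]
            return [t0, t0 + w, t0 + w + g, t0 + 2 * w + g]
        if k == "ramp":
            return [p["t_on"], p["t_on"] + p["amplitude"] / p["slope"]]
        if k == "ramp_then_step":
            t0, s, a, g, w = p["t_on"], p["slope"], p["amplitude"], p["gap"], p["width"]
            t1 = t0 + a / s
            return [t0, t1, t1 + g, t1 + g + w]
        if k == "negative_pulse":
            return [p["t_on"], p["t_on"] + p["width"]]
        return []

    def support(self, t_end: float) -> tuple[float, float]:
        """(onset, end) of the driven epoch within a trace of length ``t_end``."""
        p = self.params
        k = self.kind
        t_on = p["t_on"]
        if k in ("step", "negative_step", "ramp"):
            return t_on, t_end
        if k == "pulse_train":
            return t_on, t_on + (int(p["count"]) - 1) * p["period"] + p["width"]
        if k == "paired_pulse":
            return t_on, t_on + 2 * p["width"] + p["gap"]
        if k == "ramp_then_step":
            t1 = t_on + p["amplitude"] / p["slope"]
            return t_on, t1 + p["gap"] + p["width"]
        if k == "negative_pulse":
            return t_on, t_on + p["width"]
        return t_on, t_end  # pragma: no cover


def make_stimulus(kind: str, **params: float) -> Stimulus:
    """Build and validate a stimulus waveform.

    Raises
    ------
    ConfigurationError
        Unknown kind, missing parameter, or a sign/ordering violation
        (negative_* kinds must have amplitude <= 0, positive kinds > 0).
    """
    if kind not in _REQUIRED:
        raise ConfigurationError(
            f"unknown stimulus kind {kind!r}; expected one of {sorted(_REQUIRED)}"
        )
    missing = [k for k in _REQUIRED[kind] if k not in params]
    if missing:
        raise ConfigurationError(f"stimulus {kind!r} missing parameter(s): {missing}")
    extra = set(params) - set(_REQUIRED[kind])
    if extra:
        raise ConfigurationError(f"stimulus {kind!r} got unexpected parameter(s): {sorted(extra)}")
    p = dict(params)
    if p["t_on"] < 0:
        raise ConfigurationError(f"t_on must be >= 0, got {p['t_on']}")
    if kind.startswith("negative"):
        if p["amplitude"] > 0:
            raise ConfigurationError(
                f"stimulus {kind!r} must have amplitude <= 0, got {p['amplitude']}"
            )
    else:
        if p["amplitude"] <= 0:
            raise ConfigurationError(
                f"stimulus {kind!r} must have amplitude > 0, got {p['amplitude']}"
            )
    for name in ("width", "period", "gap", "slope"):
        if name in p and p[name] <= 0:
            raise ConfigurationError(f"stimulus parameter {name!r} must be > 0, got {p[name]}")
    if kind == "pulse_train":
        p["count"] = int(p["count"])
        if p["count"] < 1:
            raise ConfigurationError(f"pulse_train count must be >= 1, got {p['count']}")
        if p["width"] >= p["period"]:
            raise ConfigurationError("pulse_train width must be smaller than period")
    return Stimulus(kind=kind, params=p)
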