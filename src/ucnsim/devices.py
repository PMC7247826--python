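"""Phenomenological device models: the hysteretic SCR and the idealized axon stage.

The firing element of the ultra-compact neuron is a silicon controlled
rectifier (SCR, thyristor).  Forward biased, it has *two* resistive states:

* **blocking** — a high resistance ``r_off``; it switches to the conducting
  state when the anode–cathode voltage reaches a gate-dependent breakover
  threshold;
* **conducting** — a low resistance ``r_on`` in series with a forward drop
  ``v_on``; it switches back to blocking only when the anode current falls
  below the small holding current ``i_hold``.

Because the branch taken at a given voltage depends on history, the I–V
characteristic is hysteretic (memristive).  The gate electrode lowers the
breakover threshold: here the whole gate network is collapsed to a single
scalar "gate drive" voltage mapped linearly (with clamping) onto the
threshold via ``alpha_gate``.

The axon stage of the circuit (two transistors that strengthen and re-invert
the current pulse) is modelled as a memoryless comparator on the anode
current: it contributes no dynamics, only the rectangular output pulse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .exceptions import ConfigurationError, InputError

__all__ = [
    "SCRParams",
    "SCRState",
    "AxonParams",
    "scr_current",
    "effective_threshold",
    "scr_next_state",
    "axon_output",
]


@dataclass(frozen=True)
class SCRParams:
    """Parameters of the hysteretic threshold-switching element (SI units).

    Attributes
    ----------
    v_th0 : float
        Anode–cathode breakover threshold at zero gate drive [V].
    v_th_min : float
        Threshold floor under maximal gate drive [V].
    alpha_gate : float
        Threshold reduction per unit gate-drive voltage [V/V].
    i_hold : float
        Holding current below which the conducting state collapses [A].
    r_off : float
        Blocking-state resistance [ohm].
    r_on : float
        Conducting-state resistance [ohm].
    v_on : float
        Forward drop in the conducting state [V].
    """

    v_th0: float = 2.0
    v_th_min: float = 0.5
    alpha_gate: float = 0.0
    i_hold: float = 1e-5
    r_off: float = 1e7
    r_on: float = 10.0
    v_on: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.v_th_min <= self.v_th0):
            raise ConfigurationError(
                f"SCR thresholds must satisfy 0 < v_th_min <= v_th0, "
                f"got v_th_min={self.v_th_min}, v_th0={self.v_th0}"
            )
        if not self.r_on < self.r_off:
            raise ConfigurationError(
                f"SCR resistances must satisfy r_on < r_off, got r_on={self.r_on}, r_off={self.r_off}"
            )
        if self.i_hold <= 0:
            raise ConfigurationError(f"i_hold must be positive, got {self.i_hold}")
        if self.v_on < 0:
            raise ConfigurationError(f"v_on must be non-negative, got {self.v_on}")
        if self.alpha_gate < 0:
            raise ConfigurationError(f"alpha_gate must be non-negative, got {self.alpha_gate}")


@dataclass(frozen=True)
class SCRState:
    """Discrete state of the SCR: which resistive branch it is on."""

    conducting: bool = False
    last_switch_time: float = -math.inf


@dataclass(frozen=True)
class AxonParams:
    """Idealized output (axon) stage: a comparator on the anode current.

    Emits ``v_pulse`` volts while the anode current is at or above
    ``i_trigger``, zero otherwise.  Saturating, not proportional.
    """

    i_trigger: float = 1e-3
    v_pulse: float = 5.0

    def __post_init__(self) -> None:
        if self.i_trigger <= 0:
            raise ConfigurationError(f"i_trigger must be positive, got {self.i_trigger}")
        if self.v_pulse <= 0:
            raise ConfigurationError(f"v_pulse must be positive, got {self.v_pulse}")


def _scr_current(conducting: bool, v_ak: float, params: SCRParams) -> float:
    # Fast core used by the integrator right-hand side (bool instead of SCRState).
    if not math.isfinite(v_ak):
        raise InputError(f"anode-cathode voltage must be finite, got {v_ak}")
    if v_ak < 0.0:
        # Reverse bias blocks (diode-like) in both states.
        return v_ak / params.r_off
    if conducting:
        return max(0.0, v_ak - params.v_on) / params.r_on
    return v_ak / params.r_off


def scr_current(state: SCRState, v_ak: float, params: SCRParams) -> float:
    """Anode current [A] through the SCR at anode–cathode voltage ``v_ak``.

    Blocking: ohmic through ``r_off``.  Conducting: ``max(0, v_ak - v_on) / r_on``.
    Reverse bias (``v_ak < 0``): ohmic through ``r_off`` in both states.
    """
    return _scr_current(state.conducting, v_ak, params)


def effective_threshold(v_gate_drive: float, params: SCRParams) -> float:
    """Gate-modulated breakover threshold [V].

    ``clamp(v_th0 - alpha_gate * v_gate_drive, v_th_min, v_th0)`` — monotone
    non-increasing in the gate drive, bounded between the floor and the
    zero-drive value.
    """
    if not math.isfinite(v_gate_drive) or v_gate_drive < 0.0:
        raise InputError(f"gate drive must be finite and non-negative, got {v_gate_drive}")
    v = params.v_th0 - params.alpha_gate * v_gate_drive
    return min(params.v_th0, max(params.v_th_min, v))


def scr_next_state(
    state: SCRState,
    v_ak: float,
    i_ak: float,
    v_gate_drive: float,
    t: float,
    params: SCRParams,
) -> SCRState:
    """Pure discrete transition map of the SCR.

    blocking → conducting iff ``v_ak >= effective_threshold(v_gate_drive)``;
    conducting → blocking iff ``i_ak <= i_hold``; otherwise unchanged.
    """
    if state.conducting:
        if i_ak <= params.i_hold:
            return replace(state, conducting=False, last_switch_time=t)
        return state
    if v_ak >= effective_threshold(v_gate_drive, params):
        return replace(state, conducting=True, last_switch_time=t)
    return state


def axon_output(i_ak: float, params: AxonParams) -> float:
    """Memoryless output stage: ``v_pulse`` iff ``i_ak >= i_trigger`` else 0."""
    return params.v_pulse if i_ak >= params.i_trigger else 0.0
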