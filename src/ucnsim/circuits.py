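"""Circuit variants of the ultra-compact neuron, compiled to hybrid systems.

Every variant shares the same soma: a membrane capacitor ``c1`` that
integrates the input current, a leak resistor ``r_leak``, and the SCR across
the membrane node that fires (discharges the capacitor) when the membrane
voltage reaches the breakover threshold.  The variants differ only in the
input network and in an optional feedback loop:

``base``
    Current source straight into the membrane node.  One continuous state,
    ``v_mem``.
``phasic``
    An RC differentiator at the input: the source drives the node through a
    series capacitor ``c_in`` (+ series resistor ``r_in``), so only
    *changes* of the input pass.  States ``v_mem, v_cin``.
``mixed``
    Differentiator plus a parallel DC path ``r_dc`` — an onset surge rides
    on a sustained drive.  States ``v_mem, v_cin``.
``adaptive``
    Spike-triggered feedback variable ``w_fb`` (jumps by ``beta_fb`` per
    output pulse, decays with ``r_fb * c_fb``) that drives the SCR gate
    (threshold lowering via ``alpha_gate``) and/or shunts the membrane with
    conductance ``g_shunt * w_fb``.  States ``v_mem, w_fb``.
``inhibitory``
    The base topology with the SCR orientation mirrored (``polarity = -1``):
    the neuron integrates *negative* input and fires when ``-v_mem`` reaches
    the threshold.

For phasic/mixed variants the current-source amplitude is converted to a
Thevenin source voltage ``v_src = u * r_in`` driving the input network, so
the stimulus amplitude keeps its meaning as the current delivered into a
discharged circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .devices import (
    AxonParams,
    SCRParams,
    _scr_current,
    axon_output,
    effective_threshold,
)
from .exceptions import ConfigurationError
from .stimuli import Stimulus, make_stimulus  # noqa: F401  (re-exported)

__all__ = ["CircuitParams", "HybridSystem", "build_circuit", "membrane_derivative",
           "Stimulus", "make_stimulus", "VARIANTS"]

VARIANTS = ("base", "phasic", "mixed", "adaptive", "inhibitory")


@dataclass(frozen=True)
class CircuitParams:
    """Passive-network parameters of a neuron circuit (SI units).

    ``c_in = 0`` disables the differentiator path, ``r_dc = None`` disables
    the DC input path, ``beta_fb = 0`` disables the feedback loop.
    """

    c1: float = 1e-9
    r_leak: float = 1e6
    r_in: float = 1e6
    c_in: float = 0.0
    r_dc: float | None = None
    c_fb: float = 0.0
    r_fb: float = 0.0
    beta_fb: float = 0.0
    g_shunt: float = 0.0
    polarity: int = 1

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.r_leak <= 0 or self.r_in <= 0:
            raise ConfigurationError(
                f"c1, r_leak, r_in must be positive, got c1={self.c1}, "
                f"r_leak={self.r_leak}, r_in={self.r_in}"
            )
        for name in ("c_in", "c_fb", "r_fb", "beta_fb", "g_shunt"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.r_dc is not None and self.r_dc <= 0:
            raise ConfigurationError(f"r_dc must be positive (or None to disable), got {self.r_dc}")
        if self.polarity not in (1, -1):
            raise ConfigurationError(f"polarity must be +1 or -1, got {self.polarity}")

    @property
    def tau(self) -> float:
        """Membrane time constant c1 * r_leak [s]."""
        return self.c1 * self.r_leak


@dataclass
class HybridSystem:
    """A circuit compiled to continuous states + SCR discrete state + events.

    Continuous state vector ``x`` (ordering in ``state_names``):
    ``v_mem`` always first; ``v_cin`` (voltage on the input capacitor) for
    phasic/mixed; ``w_fb`` (feedback variable, volts) for adaptive.

    The two event functions bound the discrete SCR state:
    ``g_up = v_ak - effective_threshold`` (armed while blocking) and
    ``g_down = i_ak - i_hold`` (armed while conducting).
    """

    variant: str
    circuit: CircuitParams
    scr: SCRParams
    axon: AxonParams
    state_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.variant in ("base", "inhibitory"):
            self.state_names = ("v_mem",)
        elif self.variant in ("phasic", "mixed"):
            self.state_names = ("v_mem", "v_cin")
        elif self.variant == "adaptive":
            self.state_names = ("v_mem", "w_fb")
        else:  # pragma: no cover - guarded by build_circuit
            raise ConfigurationError(f"unknown variant {self.variant!r}")

    # -- geometry -----------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_events(self) -> int:
        return 2

    def initial_state(self) -> np.ndarray:
        return np.zeros(self.n_states)

    # -- continuous-state maps ---------------------------------------------

    def v_ak(self, x) -> float:
        """Anode-cathode voltage seen by the SCR (polarity-mirrored)."""
        return self.circuit.polarity * x[0]

    def gate_drive(self, x) -> float:
        """Scalar gate-drive voltage (the feedback variable, if present)."""
        if self.variant == "adaptive":
            return max(0.0, x[1])
        return 0.0

    def threshold(self, x) -> float:
        return effective_threshold(self.gate_drive(x), self.scr)

    def i_ak(self, x, conducting: bool) -> float:
        """Anode current through the SCR [A]."""
        return _scr_current(conducting, self.v_ak(x), self.scr)

    def branch_currents(self, t: float, x, u: float, conducting: bool) -> dict[str, float]:
        """Signed currents into the membrane node (positive charges ``c1``)."""
        cc = self.circuit
        v = x[0]
        currents = {"leak": -v / cc.r_leak,
                    "device": -cc.polarity * self.i_ak(x, conducting)}
        if self.variant in ("base", "inhibitory"):
            currents["input"] = u
        elif self.variant in ("phasic", "mixed"):
            v_src = u * cc.r_in
            v_cin = x[1]
            currents["input"] = (v_src - v_cin - v) / cc.r_in
            if cc.r_dc is not None:
                currents["dc"] = (v_src - v) / cc.r_dc
        elif self.variant == "adaptive":
            currents["input"] = u
            currents["shunt"] = -cc.g_shunt * max(0.0, x[1]) * v
        return currents

    def rhs(self, t: float, x, u: float, conducting: bool) -> np.ndarray:
        """Time derivatives of the continuous state."""
        cc = self.circuit
        currents = self.branch_currents(t, x, u, conducting)
        dv = sum(currents.values()) / cc.c1
        if self.variant in ("base", "inhibitory"):
            return np.array([dv])
        if self.variant in ("phasic", "mixed"):
            dv_cin = currents["input"] / cc.c_in
            return np.array([dv, dv_cin])
        # adaptive
        dw = -x[1] / (cc.r_fb * cc.c_fb)
        return np.array([dv, dw])

    # -- discrete maps ------------------------------------------------------

    def apply_spike(self, x) -> np.ndarray:
        """Per-spike jump of the feedback variable (adaptive variant only)."""
        if self.variant == "adaptive" and self.circuit.beta_fb > 0:
            x = np.array(x, dtype=float)
            x[1] += self.circuit.beta_fb
        return np.asarray(x, dtype=float)

    def g_up(self, t: float, x) -> float:
        """Threshold-crossing event function (armed while blocking)."""
        return self.v_ak(x) - self.threshold(x)

    def g_down(self, t: float, x) -> float:
        """Holding-current event function (armed while conducting)."""
        return self.i_ak(x, True) - self.scr.i_hold

    def output(self, x, conducting: bool) -> tuple[float, float]:
        """Output map: (v_mem [V], v_out [V])."""
        return float(x[0]), axon_output(self.i_ak(x, conducting), self.axon)


def membrane_derivative(t: float, x, u: float, conducting: bool, system: HybridSystem):
    """State rates of ``system`` at time ``t`` — module-level alias of ``HybridSystem.rhs``."""
    return system.rhs(t, x, u, conducting)


def build_circuit(
    variant_id: str,
    circuit: CircuitParams | None = None,
    scr: SCRParams | None = None,
    axon: AxonParams | None = None,
) -> HybridSystem:
    """Compile a circuit variant into a :class:`HybridSystem`.

    Raises
    ------
    ConfigurationError
        If the variant requires an element the parameters disable (e.g.
        ``phasic`` with ``c_in = 0``), naming the missing element.
    """
    circuit = circuit if circuit is not None else CircuitParams()
    scr = scr if scr is not None else SCRParams()
    axon = axon if axon is not None else AxonParams()

    if variant_id not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant_id!r}; expected one of {VARIANTS}")
    if variant_id in ("phasic", "mixed") and circuit.c_in <= 0:
        raise ConfigurationError(f"variant {variant_id!r} requires c_in > 0 (differentiator capacitor)")
    if variant_id == "phasic" and circuit.r_dc is not None:
        raise ConfigurationError("variant 'phasic' must not enable the DC path (r_dc); use 'mixed'")
    if variant_id == "mixed" and circuit.r_dc is None:
        raise ConfigurationError("variant 'mixed' requires r_dc (parallel DC input path)")
    if variant_id == "adaptive":
        if circuit.beta_fb <= 0:
            raise ConfigurationError("variant 'adaptive' requires beta_fb > 0 (per-spike feedback jump)")
        if circuit.c_fb <= 0 or circuit.r_fb <= 0:
            raise ConfigurationError("variant 'adaptive' requires c_fb > 0 and r_fb > 0 (feedback decay)")
    if variant_id == "inhibitory":
        if circuit.polarity != -1:
            raise ConfigurationError("variant 'inhibitory' requires polarity = -1")
        if circuit.c_in != 0 or circuit.beta_fb != 0:
            raise ConfigurationError("variant 'inhibitory' supports only the base topology (c_in = beta_fb = 0)")
    if variant_id != "inhibitory" and circuit.polarity != 1:
        raise ConfigurationError(f"variant {variant_id!r} requires polarity = +1")

    return HybridSystem(variant=variant_id, circuit=circuit, scr=scr, axon=axon)
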