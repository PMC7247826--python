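"""Spike-train analytics and the behavior classifier.

Spikes are onsets of the output pulse (upward crossings of ``v_out``
through ``v_half``).  From the spike train we derive interspike intervals
(ISIs), the adaptation index, bursts, first-spike latency and f-I curves,
and apply a fixed-order predicate table mapping a (stimulus, trace) pair to
one of the behavior labels of the Izhikevich catalogue that the circuit
family reproduces.

Single-trace predicates (in evaluation order, first match wins; negative-
polarity stimuli are dispatched to their own branch first so a rebound
spike is not mistaken for phasic spiking):

========================  =====================================================
tonic_spiking             >=5 spikes spanning >80% of the driven epoch, |AI|<0.1
phasic_spiking            exactly 1 spike, within 5*tau of onset
phasic_bursting           exactly 1 burst (>=2 spikes), no spikes outside it
mixed                     an onset burst followed by >=3 non-burst spikes
spike_frequency_adaptation >=5 spikes, strictly increasing ISIs, AI >= 0.15
spike_latency             first-spike latency > 3x the tonic reference
                          latency tau*ln(3) (the latency at 1.5x threshold)
========================  =====================================================

Class 1/2 excitability, integrator and accommodation are multi-run
predicates combined at the scenario level (see :mod:`ucnsim.scenario`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import AnalysisError
from .stimuli import Stimulus
from .trace import Trace

__all__ = [
    "SpikeTrain",
    "BEHAVIOR_LABELS",
    "ClassifierRules",
    "detect_spikes",
    "interspike_intervals",
    "adaptation_index",
    "detect_bursts",
    "f_i_curve",
    "classify_excitability",
    "latency",
    "classify_behavior",
]

BEHAVIOR_LABELS = (
    "tonic_spiking",
    "phasic_spiking",
    "phasic_bursting",
    "mixed",
    "spike_frequency_adaptation",
    "class1_excitable",
    "class2_excitable",
    "spike_latency",
    "integrator",
    "accommodation",
    "rebound_spike",
    "inhibition_induced_spiking",
    "silent",
    "unclassified",
)


@dataclass(frozen=True)
class SpikeTrain:
    """Onset times [s] of output pulses, strictly increasing."""

    times: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise AnalysisError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ClassifierRules:
    """Thresholds of the predicate table (SI units; defaults for tau = 1 ms).

    ``tau`` is the scenario's membrane time constant; windows expressed in
    multiples of tau (onset window, latency reference) scale with it.
    Scenario fixtures override the ISI thresholds to match their time scale.
    """

    v_half: float = 2.5
    t_refractory: float = 2e-4
    isi_intra: float = 3e-3
    isi_inter: float = 15e-3
    f_eps: float = 2.0
    f_jump: float = 20.0
    tau: float = 1e-3
    min_tonic_spikes: int = 5
    ai_tonic: float = 0.1
    ai_adapt: float = 0.15
    span_tonic: float = 0.8
    latency_factor: float = 3.0
    onset_window_tau: float = 5.0


def detect_spikes(trace: Trace, v_half: float, t_refractory: float = 2e-4) -> SpikeTrain:
    """Spike onsets: upward crossings of ``v_out`` through ``v_half``.

    Crossings closer than ``t_refractory`` are merged into one onset.
    """
    if len(trace) == 0:
        raise AnalysisError("cannot detect spikes on an empty trace")
    if t_refractory < 0:
        raise AnalysisError(f"t_refractory must be >= 0, got {t_refractory}")
    v = trace.v_out
    above = v >= v_half
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    onsets: list[float] = []
    for idx in rising:
        t_cross = float(trace.t[idx])
        if not onsets or t_cross - onsets[-1] > t_refractory:
            onsets.append(t_cross)
    return SpikeTrain(times=np.array(onsets))


def interspike_intervals(train: SpikeTrain) -> np.ndarray:
    """Successive spike-time differences [s]; needs >= 2 spikes."""
    if len(train) < 2:
        raise AnalysisError(f"need >= 2 spikes for ISIs, got {len(train)}")
    return np.diff(train.times)


def adaptation_index(isis) -> float:
    """(last - first) / (last + first) of the ISI sequence — in (-1, 1).

    Zero for a regular train, positive when firing slows down, negative when
    it speeds up; antisymmetric under ISI reversal.
    """
    isis = np.asarray(isis, dtype=float)
    if len(isis) < 2:
        raise AnalysisError(f"need >= 2 ISIs for the adaptation index, got {len(isis)}")
    return float((isis[-1] - isis[0]) / (isis[-1] + isis[0]))


def detect_bursts(train: SpikeTrain, isi_intra: float, isi_inter: float) -> list[np.ndarray]:
    """Maximal spike groups with internal gaps <= ``isi_intra``.

    A group qualifies as a burst only if it has >= 2 spikes and is separated
    from neighboring spikes by >= ``isi_inter``.  Singletons are never bursts.
    """
    if not isi_intra < isi_inter:
        raise AnalysisError(
            f"burst thresholds must satisfy isi_intra < isi_inter, "
            f"got {isi_intra} >= {isi_inter}"
        )
    times = train.times
    if len(times) == 0:
        return []
    gaps = np.diff(times)
    splits = np.flatnonzero(gaps > isi_intra) + 1
    groups = np.split(times, splits)
    bursts = []
    for gi, grp in enumerate(groups):
        if len(grp) < 2:
            continue
        ok_before = gi == 0 or grp[0] - groups[gi - 1][-1] >= isi_inter
        ok_after = gi == len(groups) - 1 or groups[gi + 1][0] - grp[-1] >= isi_inter
        if ok_before and ok_after:
            bursts.append(grp)
    return bursts


def f_i_curve(
    build_run,
    amplitudes,
    duration: float,
    *,
    v_half: float = 2.5,
    t_refractory: float = 2e-4,
    dt_max: float = 1e-4,
    sample_dt: float = 1e-5,
) -> list[tuple[float, float]]:
    """Steady-state firing frequency vs input amplitude.

    ``build_run(amplitude)`` must return ``(system, stimulus)``.  The
    frequency at each amplitude is ``(n - 1) / (t_last - t_first)`` over the
    spikes in the second half of the window, 0 if fewer than two spikes land
    there.  Amplitudes must be sorted ascending.
    """
    from .simulate import simulate  # local import to avoid a cycle

    amplitudes = list(amplitudes)
    if any(b <= a for a, b in zip(amplitudes, amplitudes[1:])):
        raise AnalysisError("amplitudes must be sorted strictly ascending")
    out: list[tuple[float, float]] = []
    for amp in amplitudes:
        system, stim = build_run(amp)
        try:
            trace = simulate(system, stim, duration, dt_max=dt_max, sample_dt=sample_dt)
        except Exception as exc:
            raise AnalysisError(f"simulation failed at amplitude {amp!r}: {exc}") from exc
        spikes = detect_spikes(trace, v_half, t_refractory).times
        late = spikes[spikes >= duration / 2]
        if len(late) >= 2:
            f = (len(late) - 1) / (late[-1] - late[0])
        else:
            f = 0.0
        out.append((float(amp), float(f)))
    return out


def classify_excitability(
    fi: list[tuple[float, float]], f_eps: float, f_jump: float
) -> str:
    """Hodgkin's classification from an f-I curve.

    Class 1: the minimum nonzero frequency is below ``f_eps`` (the rate
    grows continuously from zero).  Class 2: the frequency jumps from 0 to
    at least ``f_jump`` between adjacent amplitudes.  A curve that is all
    zero or all nonzero is unclassified.
    """
    freqs = [f for _, f in fi]
    nonzero = [f for f in freqs if f > 0]
    if not nonzero or not any(f == 0 for f in freqs):
        return "unclassified"
    if min(nonzero) < f_eps:
        return "class1_excitable"
    for (_, f0), (_, f1) in zip(fi, fi[1:]):
        if f0 == 0 and f1 >= f_jump:
            return "class2_excitable"
    return "unclassified"


def latency(train: SpikeTrain, t_on: float) -> float:
    """First-spike latency [s] after stimulus onset; needs >= 1 spike after ``t_on``."""
    after = train.times[train.times >= t_on]
    if len(after) == 0:
        raise AnalysisError(f"no spikes at or after stimulus onset t_on={t_on}")
    return float(after[0] - t_on)


def _tonic_reference_latency(rules: ClassifierRules) -> float:
    # Charge-up time from rest to threshold at 1.5x the rheobase drive:
    # t = tau * ln(A / (A - v_th)) with A = 1.5 * v_th  ->  tau * ln 3.
    return rules.tau * math.log(3.0)


def classify_behavior(trace: Trace, stimulus: Stimulus, rules: ClassifierRules | None = None) -> str:
    """Map a (stimulus, trace) pair to a behavior label (total, deterministic)."""
    rules = rules if rules is not None else ClassifierRules()
    spikes = detect_spikes(trace, rules.v_half, rules.t_refractory)
    if len(spikes) == 0:
        return "silent"
    t_on, t_off = stimulus.support(trace.t_end)
    first = float(spikes.times[0])

    if stimulus.kind.startswith("negative"):
        if stimulus.kind == "negative_pulse":
            during = spikes.times[(spikes.times >= t_on) & (spikes.times < t_off)]
            after = spikes.times[
                (spikes.times >= t_off)
                & (spikes.times <= t_off + rules.onset_window_tau * rules.tau)
            ]
            if len(during) == 0 and len(after) >= 1:
                return "rebound_spike"
            return "unclassified"
        # sustained negative drive
        during = spikes.times[spikes.times >= t_on]
        if len(during) >= rules.min_tonic_spikes:
            return "inhibition_induced_spiking"
        return "unclassified"

    n = len(spikes)
    isis = np.diff(spikes.times) if n >= 2 else np.array([])
    ai = adaptation_index(isis) if len(isis) >= 2 else 0.0
    span = (spikes.times[-1] - t_on) / max(t_off - t_on, 1e-300)
    bursts = detect_bursts(spikes, rules.isi_intra, rules.isi_inter)
    in_burst = np.zeros(n, dtype=bool)
    for b in bursts:
        in_burst |= np.isin(spikes.times, b)

    if n >= rules.min_tonic_spikes and span > rules.span_tonic and abs(ai) < rules.ai_tonic:
        return "tonic_spiking"
    if n == 1 and first - t_on <= rules.onset_window_tau * rules.tau:
        return "phasic_spiking"
    if len(bursts) == 1 and len(bursts[0]) == n:
        return "phasic_bursting"
    if bursts and bursts[0][0] == spikes.times[0]:
        n_tail = int(np.sum(~in_burst & (spikes.times > bursts[0][-1])))
        if n_tail >= 3:
            return "mixed"
    if n >= rules.min_tonic_spikes and np.all(np.diff(isis) > 0) and ai >= rules.ai_adapt:
        return "spike_frequency_adaptation"
    if first - t_on > rules.latency_factor * _tonic_reference_latency(rules):
        return "spike_latency"
    return "unclassified"
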