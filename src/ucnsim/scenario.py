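"""Scenario configs: one JSON file per behavior, end-to-end execution.

A scenario bundles a circuit variant, device parameters, one or more
stimuli, classifier rule thresholds and the expected behavior label.  All
numeric fields are SI.  Protocols:

``single``
    One stimulus, one simulation, single-trace classification.
``pulse_pair``
    Two paired-pulse stimuli (short and long gap); label is ``integrator``
    iff the short-gap run fires and the long-gap run is silent.
``ramp_vs_step``
    Two stimuli of equal peak amplitude, slow ramp then abrupt step; label
    is ``accommodation`` iff the ramp run is silent and the step run fires.
``fi``
    A step-stimulus template swept over ``amplitudes``; label from the f-I
    curve via :func:`ucnsim.analysis.classify_excitability`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .analysis import (
    BEHAVIOR_LABELS,
    ClassifierRules,
    adaptation_index,
    classify_behavior,
    classify_excitability,
    detect_spikes,
    f_i_curve,
    latency,
)
from .circuits import CircuitParams, build_circuit
from .devices import AxonParams, SCRParams
from .exceptions import ConfigurationError
from .simulate import simulate
from .stimuli import Stimulus, make_stimulus
from .trace import Trace, write_trace

__all__ = ["Scenario", "run_scenario"]

PROTOCOLS = ("single", "pulse_pair", "ramp_vs_step", "fi")

_EXPECTED_KEYS = {
    "scenario_id", "variant", "protocol", "expected_label", "duration_s",
    "dt_max_s", "sample_dt_s", "circuit", "scr", "axon", "stimulus",
    "amplitudes", "rules", "description",
}


def _build_params(cls, d: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - valid
    if unknown:
        raise ConfigurationError(f"unknown field(s) in {section!r}: {sorted(unknown)}")
    try:
        return cls(**d)
    except TypeError as exc:
        raise ConfigurationError(f"invalid {section!r} section: {exc}") from exc


@dataclass
class Scenario:
    """A validated scenario configuration."""

    scenario_id: str
    variant: str
    protocol: str
    expected_label: str
    duration_s: float
    circuit: CircuitParams
    scr: SCRParams
    axon: AxonParams
    stimuli: list[Stimulus]
    rules: ClassifierRules
    dt_max_s: float = 1e-4
    sample_dt_s: float = 1e-6
    amplitudes: list[float] | None = None
    description: str = ""

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        unknown = set(d) - _EXPECTED_KEYS
        if unknown:
            raise ConfigurationError(f"unknown scenario key(s): {sorted(unknown)}")
        for key in ("scenario_id", "variant", "expected_label", "duration_s", "stimulus"):
            if key not in d:
                raise ConfigurationError(f"scenario missing required key {key!r}")
        protocol = d.get("protocol", "single")
        if protocol not in PROTOCOLS:
            raise ConfigurationError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
        expected = d["expected_label"]
        if expected not in BEHAVIOR_LABELS:
            raise ConfigurationError(f"unknown expected_label {expected!r}")

        circuit = _build_params(CircuitParams, d.get("circuit", {}), "circuit")
        scr = _build_params(SCRParams, d.get("scr", {}), "scr")
        axon = _build_params(AxonParams, d.get("axon", {}), "axon")

        stim_spec = d["stimulus"]
        if isinstance(stim_spec, dict):
            stim_spec = [stim_spec]
        stimuli = []
        for s in stim_spec:
            s = dict(s)
            kind = s.pop("kind", None)
            if kind is None:
                raise ConfigurationError(
                    f"scenario {d['scenario_id']!r}: stimulus entry missing 'kind'"
                )
            stimuli.append(make_stimulus(kind, **s))
        n_expected = {"single": 1, "fi": 1, "pulse_pair": 2, "ramp_vs_step": 2}[protocol]
        if len(stimuli) != n_expected:
            raise ConfigurationError(
                f"protocol {protocol!r} needs {n_expected} stimulus entries, got {len(stimuli)}"
            )

        amplitudes = d.get("amplitudes")
        if protocol == "fi":
            if not amplitudes or len(amplitudes) < 2:
                raise ConfigurationError("protocol 'fi' requires an 'amplitudes' list (>= 2 values)")
            amplitudes = [float(a) for a in amplitudes]

        rules_d = dict(d.get("rules", {}))
        rules_d.setdefault("v_half", axon.v_pulse / 2)
        rules_d.setdefault("tau", circuit.tau)
        rules = _build_params(ClassifierRules, rules_d, "rules")

        duration = float(d["duration_s"])
        if duration <= 0:
            raise ConfigurationError(f"duration_s must be positive, got {duration}")

        return cls(
            scenario_id=str(d["scenario_id"]),
            variant=d["variant"],
            protocol=protocol,
            expected_label=expected,
            duration_s=duration,
            circuit=circuit,
            scr=scr,
            axon=axon,
            stimuli=stimuli,
            rules=rules,
            dt_max_s=float(d.get("dt_max_s", 1e-4)),
            sample_dt_s=float(d.get("sample_dt_s", 1e-6)),
            amplitudes=amplitudes,
            description=str(d.get("description", "")),
        )

    @classmethod
    def from_json(cls, path) -> "Scenario":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ConfigurationError(f"invalid JSON in {path}: {exc}") from exc
        return cls.from_dict(d)

    def build_system(self):
        return build_circuit(self.variant, self.circuit, self.scr, self.axon)


def _simulate_scenario(scenario: Scenario, stimulus: Stimulus) -> Trace:
    return simulate(
        scenario.build_system(),
        stimulus,
        scenario.duration_s,
        dt_max=scenario.dt_max_s,
        sample_dt=scenario.sample_dt_s,
    )


def _metrics_from_trace(trace: Trace, stimulus: Stimulus, rules: ClassifierRules) -> dict:
    spikes = detect_spikes(trace, rules.v_half, rules.t_refractory)
    m: dict = {"n_spikes": len(spikes)}
    if len(spikes) >= 1:
        t_on, _ = stimulus.support(trace.t_end)
        m["latency_s"] = latency(spikes, t_on)
    if len(spikes) >= 3:
        m["adaptation_index"] = adaptation_index(np.diff(spikes.times))
    return m


def run_scenario(scenario: Scenario, out_dir=None) -> dict:
    """Execute a scenario end-to-end and classify the outcome.

    Returns a record dict (observed vs expected label, metrics, trace file
    names).  Simulation failures are captured in the record rather than
    raised, so a battery run can continue.
    """
    record: dict = {
        "scenario_id": scenario.scenario_id,
        "expected_label": scenario.expected_label,
        "observed_label": None,
        "metrics": {},
        "trace_files": [],
        "pass": False,
        "error": None,
    }
    out_dir = Path(out_dir) if out_dir is not None else None

    def save(trace: Trace, suffix: str = "") -> None:
        if out_dir is None:
            return
        out_dir.mkdir(parents=True, exist_ok=True)
        name = f"{scenario.scenario_id}{suffix}.csv"
        write_trace(trace, out_dir / name)
        record["trace_files"].append(name)

    try:
        if scenario.protocol == "single":
            trace = _simulate_scenario(scenario, scenario.stimuli[0])
            save(trace)
            record["observed_label"] = classify_behavior(trace, scenario.stimuli[0], scenario.rules)
            record["metrics"] = _metrics_from_trace(trace, scenario.stimuli[0], scenario.rules)
        elif scenario.protocol in ("pulse_pair", "ramp_vs_step"):
            traces = [_simulate_scenario(scenario, s) for s in scenario.stimuli]
            for i, tr in enumerate(traces):
                save(tr, suffix=f"_run{i + 1}" )
            counts = [
                len(detect_spikes(tr, scenario.rules.v_half, scenario.rules.t_refractory))
                for tr in traces
            ]
            if scenario.protocol == "pulse_pair":
                # stimuli order: (short gap, long gap)
                if counts[0] >= 1 and counts[1] == 0:
                    record["observed_label"] = "integrator"
                elif counts[0] == 0 and counts[1] == 0:
                    record["observed_label"] = "silent"
                else:
                    record["observed_label"] = "unclassified"
            else:
                # stimuli order: (slow ramp, equal-amplitude step)
                if counts[0] == 0 and counts[1] >= 1:
                    record["observed_label"] = "accommodation"
                elif counts[0] == 0 and counts[1] == 0:
                    record["observed_label"] = "silent"
                else:
                    record["observed_label"] = "unclassified"
            record["metrics"] = {"n_spikes_per_run": counts}
        elif scenario.protocol == "fi":
            template = scenario.stimuli[0]

            def build_run(amp):
                params = dict(template.params)
                params["amplitude"] = amp
                return scenario.build_system(), make_stimulus(template.kind, **params)

            fi = f_i_curve(
                build_run,
                scenario.amplitudes,
                scenario.duration_s,
                v_half=scenario.rules.v_half,
                t_refractory=scenario.rules.t_refractory,
                dt_max=scenario.dt_max_s,
                sample_dt=scenario.sample_dt_s,
            )
            record["observed_label"] = classify_excitability(
                fi, scenario.rules.f_eps, scenario.rules.f_jump
            )
            record["metrics"] = {"f_i": [[a, f] for a, f in fi]}
            # representative trace at the largest amplitude
            system, stim = build_run(scenario.amplitudes[-1])
            trace = simulate(system, stim, scenario.duration_s,
                             dt_max=scenario.dt_max_s, sample_dt=scenario.sample_dt_s)
            save(trace)
        record["pass"] = record["observed_label"] == scenario.expected_label
    except Exception as exc:  # battery must survive individual failures
        record["observed_label"] = "failed"
        record["error"] = f"{type(exc).__name__}: {exc}"
    return record
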