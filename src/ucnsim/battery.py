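"""The shipped scenario battery: run every config, report observed vs expected."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .exceptions import ConfigurationError
from .scenario import Scenario, run_scenario

__all__ = ["BatteryReport", "run_battery", "shipped_scenario_dir", "load_scenarios"]


def shipped_scenario_dir() -> Path:
    """Directory of the scenario JSON fixtures shipped with the package."""
    return Path(resources.files("ucnsim") / "scenarios")


@dataclass
class BatteryReport:
    """Per-scenario records plus summary counts."""

    records: list[dict] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.records)

    @property
    def n_pass(self) -> int:
        return sum(1 for r in self.records if r["pass"])

    @property
    def labels_reproduced(self) -> set[str]:
        """Distinct behavior labels correctly reproduced."""
        return {r["observed_label"] for r in self.records if r["pass"]}

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_pass": self.n_pass,
            "n_distinct_behaviors": len(self.labels_reproduced),
            "records": self.records,
        }

    def summary(self) -> str:
        lines = [f"{'scenario':<28} {'expected':<28} {'observed':<28} pass"]
        for r in self.records:
            lines.append(
                f"{r['scenario_id']:<28} {r['expected_label']:<28} "
                f"{str(r['observed_label']):<28} {'yes' if r['pass'] else 'NO'}"
            )
        lines.append(
            f"{self.n_pass}/{self.n_total} scenarios passed, "
            f"{len(self.labels_reproduced)} distinct behaviors reproduced"
        )
        return "\n".join(lines)


def load_scenarios(config_dir=None) -> list[Scenario]:
    """Load and validate every ``*.json`` scenario in ``config_dir`` (sorted by name)."""
    config_dir = Path(config_dir) if config_dir is not None else shipped_scenario_dir()
    paths = sorted(config_dir.glob("*.json"))
    if not paths:
        raise ConfigurationError(f"no scenario configs (*.json) found in {config_dir}")
    scenarios = [Scenario.from_json(p) for p in paths]
    seen: set[str] = set()
    for s in scenarios:
        if s.scenario_id in seen:
            raise ConfigurationError(f"duplicate scenario_id {s.scenario_id!r} in {config_dir}")
        seen.add(s.scenario_id)
    return scenarios


def run_battery(config_dir=None, out_dir=None) -> BatteryReport:
    """Run every scenario in ``config_dir`` (shipped battery by default).

    Writes per-scenario trace CSVs and ``report.json`` into ``out_dir`` when
    given.  Fully deterministic: two executions produce identical reports
    and trace files.
    """
    scenarios = load_scenarios(config_dir)
    report = BatteryReport()
    for scenario in scenarios:
        report.records.append(run_scenario(scenario, out_dir))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
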