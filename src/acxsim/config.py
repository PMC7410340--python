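"""Run configuration, validation, serialization, and target verification."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "verify_targets"]

_KNOWN_PRESETS = ("ssa", "fws", "tca", "pv_act")
_KNOWN_TIERS = ("rate", "spiking")
_KNOWN_CONDITIONS = (
    "control", "pv_suppress", "sst_suppress", "pv_activate", "sst_activate",
)

#: Parameter overrides accepted as flat dotted keys, with validation ranges.
_OVERRIDE_RANGES: dict[str, tuple[float, float]] = {
    "rate.q": (0.0, 100.0),
    "rate.r": (1e-9, 100.0),
    "rate.tau_d1": (1.0, 1e5),
    "rate.tau_d2": (1.0, 1e5),
    "rate.w_ee": (0.0, 10.0),
    "three_unit.alpha": (1e-9, 1.0),
    "three_unit.a_dep": (0.0, 2.0),
    "three_unit.b_fac": (0.0, 10.0),
    "three_unit.F_th": (0.0, 10.0),
    "spiking.q": (0.0, 1e5),
    "opto.amplitude": (-1e5, 1e5),
}


@dataclass
class RunConfig:
    """Fully-resolved configuration of one experiment run."""

    paradigm: str = "ssa"
    tier: str = "rate"
    condition: str = "control"
    dt: float = 0.1  # ms (rate tier; the spiking tier uses 0.05)
    seed: int = 0
    n_seeds: int = 1
    overrides: dict = field(default_factory=dict)
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.paradigm not in _KNOWN_PRESETS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.tier not in _KNOWN_TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.condition not in _KNOWN_CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for key, value in self.overrides.items():
            if key not in _OVERRIDE_RANGES:
                raise ValueError(f"unknown override key {key!r}")
            lo, hi = _OVERRIDE_RANGES[key]
            if not lo <= float(value) <= hi:
                raise ValueError(
                    f"override {key}={value} outside valid range [{lo}, {hi}]"
                )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON config; unknown keys and out-of-range values raise.

    An empty file resolves to pure defaults.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def verify_targets(
    computed: dict,
    registry: dict,
) -> list[dict]:
    """Compare computed summary values against registered expectations.

    ``registry`` maps name -> {"expected": float, "kind": "deterministic" |
    "stochastic", "tol": relative tolerance (deterministic) , "sd": seed
    standard deviation (stochastic)}.  ``computed`` maps name -> float (or
    is missing, reported as "not run").  Returns one record per target.
    """
    rows = []
    for name, spec in registry.items():
        expected = spec["expected"]
        if name not in computed:
            rows.append({"target": name, "status": "not run",
                         "expected": expected, "value": None})
            continue
        value = computed[name]
        if spec.get("kind", "deterministic") == "stochastic":
            band = 3.0 * spec.get("sd", 0.0)
            ok = abs(value - expected) <= band
        else:
            tol = spec.get("tol", 0.05)
            ok = abs(value - expected) <= tol * abs(expected)
        rows.append({"target": name, "status": "pass" if ok else "fail",
                     "expected": expected, "value": value})
    return rows


def targets_exit_code(rows: list[dict]) -> int:
    return 0 if all(r["status"] in ("pass", "not run") for r in rows) else 1


def write_report(rows: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(rows, indent=1))
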