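"""Single-file run configuration for the pipeline CLI.

A YAML (or JSON) document with full defaulting; all randomness derives from
one root seed. Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from .synthetic import SimConfig, ConfigurationError
from .ingest import ExclusionWindow
from .qa import QAThresholds


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with sensible defaults."""

    out_dir: str = "aircal_out"
    raw_path: Optional[str] = None
    reference_path: Optional[str] = None
    schedule_path: Optional[str] = None
    scale: str = "hourly"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    model_ids: Dict[str, int] = field(
        default_factory=lambda: {"CO": 3, "NO": 4, "NO2": 4, "OX": 4})
    exclusion_windows: List[ExclusionWindow] = field(default_factory=list)
    qa: QAThresholds = field(default_factory=QAThresholds)
    cv_k: int = 10
    drift_min_span_days: float = 365.0
    drift_min_coloc_fraction: float = 0.20

    def validate(self, need_inputs: bool = False) -> None:
        if self.scale not in ("hourly", "daily"):
            raise ConfigurationError("scale must be 'hourly' or 'daily'")
        if self.cv_k < 2:
            raise ConfigurationError("cv_k must be >= 2")
        for st, mid in self.model_ids.items():
            if mid not in range(8):
                raise ConfigurationError(f"model_ids[{st}] must be in 0..7")
        if need_inputs:
            for name in ("raw_path", "reference_path", "schedule_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigurationError(f"{name} missing or does not exist: {p}")
        self.sim.validate()


def _build_sim(d: dict) -> SimConfig:
    allowed = {f.name for f in dataclasses.fields(SimConfig)}
    bad = set(d) - allowed
    if bad:
        raise ConfigurationError(f"unknown sim config keys: {sorted(bad)}")
    if "temp_range" in d:
        d["temp_range"] = tuple(d["temp_range"])
    if "rh_range" in d:
        d["rh_range"] = tuple(d["rh_range"])
    return SimConfig(**d)


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Load a RunConfig from YAML/JSON, apply overrides, and validate."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    bad = set(data) - allowed
    if bad:
        raise ConfigurationError(f"unknown config keys: {sorted(bad)}")

    sim_seed_given = isinstance(data.get("sim"), dict) and "seed" in data["sim"]
    if "sim" in data and isinstance(data["sim"], dict):
        data["sim"] = _build_sim(data["sim"])
    if "qa" in data and isinstance(data["qa"], dict):
        qa_allowed = {f.name for f in dataclasses.fields(QAThresholds)}
        bad = set(data["qa"]) - qa_allowed
        if bad:
            raise ConfigurationError(f"unknown qa config keys: {sorted(bad)}")
        if "range_mv" in data["qa"]:
            data["qa"]["range_mv"] = tuple(data["qa"]["range_mv"])
        data["qa"] = QAThresholds(**data["qa"])
    if "exclusion_windows" in data:
        ws = []
        for w in data["exclusion_windows"]:
            ws.append(ExclusionWindow(start=pd.Timestamp(w["start"], tz="UTC"),
                                      end=pd.Timestamp(w["end"], tz="UTC"),
                                      reason=w.get("reason", "event")))
        data["exclusion_windows"] = ws

    cfg = RunConfig(**data)
    # one root seed drives the simulator too, unless the file pins its own
    if not sim_seed_given:
        cfg.sim.seed = cfg.seed
    cfg.validate()
    return cfg


def config_digest(cfg: RunConfig) -> str:
    """Stable hash of the configuration for the run manifest."""
    import hashlib

    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, (pd.Timestamp,)):
            return str(o)
        if isinstance(o, dict):
            return {k: enc(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        return o

    blob = json.dumps(enc(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
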