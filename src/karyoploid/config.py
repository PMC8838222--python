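"""Run configuration shared by the command-line entry points.

A :class:`RunConfig` collects every tunable of the pipeline with its
module-level default, serialises to a single JSON dialect (no comments,
sorted keys) and hashes canonically so runs are reproducible and logged
runs can be compared by config fingerprint.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

from .flowcyto import DEFAULT_CV_FAIL, DEFAULT_CV_WARN, DEFAULT_FLOOR_CHANNEL, MAIZE_2C_PG
from .karyotype import DEFAULT_MEDIAN_TOLERANCE
from .ploidy import DEFAULT_ALLOWED_LEVELS, DEFAULT_BASE_X, DEFAULT_REL_TOLERANCE


@dataclass
class RunConfig:
    standard_name: str = "Zea mays"
    standard_2c_pg: float = MAIZE_2C_PG
    median_tolerance: float = DEFAULT_MEDIAN_TOLERANCE
    cv_warn_pct: float = DEFAULT_CV_WARN
    cv_fail_pct: float = DEFAULT_CV_FAIL
    floor_channel: int = DEFAULT_FLOOR_CHANNEL
    smoothing_window: int = 5
    min_prominence: float = 0.05
    rel_tolerance: float = DEFAULT_REL_TOLERANCE
    allowed_levels: tuple[int, ...] = DEFAULT_ALLOWED_LEVELS
    base_x: int = DEFAULT_BASE_X
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["allowed_levels"] = list(self.allowed_levels)
        return json.dumps(d, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "allowed_levels" in d:
            d["allowed_levels"] = tuple(d["allowed_levels"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.md5(self.to_json().encode()).hexdigest()[:12]
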