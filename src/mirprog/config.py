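"""Structured pipeline configuration.

A flat YAML mapping (optionally with an ``inputs`` section for paths)
populates :class:`PipelineConfig`; unknown keys are a hard error so a
typo never silently falls back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, with the defaults used throughout.

    ``min_supports`` are the per-stage minimum biclique supports (weeks
    6, 8, 10, 12) and ``trend_min_support`` the one used for the two
    trend networks.
    """

    inputs: dict = field(default_factory=dict)
    de_fdr_cutoff: float = 0.05
    pseudocount: float = 1.0
    discretization_k: float = 0.4
    discretization_scope: str = "pooled"
    correlation_source: str = "mixed"  # mixed | normalized | rpkm
    min_supports: tuple[int, ...] = (8, 7, 7, 6)
    trend_min_support: int = 4
    enrichment_fdr_cutoff: float = 0.05
    mb_fdr_cutoff: float = 0.05
    min_itemset_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fdr_cutoff", "enrichment_fdr_cutoff", "mb_fdr_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.discretization_k <= 0:
            raise ValueError("discretization_k must be positive")
        if any(s < 1 for s in self.min_supports) or self.trend_min_support < 1:
            raise ValueError("supports must be >= 1")
        if self.correlation_source not in ("mixed", "normalized", "rpkm"):
            raise ValueError(f"unknown correlation_source {self.correlation_source!r}")
        if self.discretization_scope not in ("pooled", "per-transition"):
            raise ValueError(f"unknown discretization_scope {self.discretization_scope!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "min_supports" in raw:
            raw["min_supports"] = tuple(raw["min_supports"])
        return cls(**raw)

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
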