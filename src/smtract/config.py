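"""Serializable run configuration tying the pipeline stages together.

All randomness flows from one root seed via named substreams (tracking
seed jitter, rater-table simulation), so a run is reproducible from its
config alone; the config hash is embedded in every output's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

from .gating import GateExtents, NotTemplateConfig
from .io import config_hash


# substream offsets derived from the root seed (kept below 2**31)
SUBSTREAM_TRACKING_LOW = 1
SUBSTREAM_TRACKING_HIGH = 2
SUBSTREAM_RATERS = 3


def substream(root_seed: int, offset: int) -> int:
    return (int(root_seed) * 1000 + offset) % (2**31 - 1)


@dataclass
class RunConfig:
    seed: int = 0
    low_step: float = 1.0
    low_angle: float = 45.0
    high_step: float = 0.5
    high_angle: float = 89.0
    fod_threshold: float = 0.1
    min_length: float = 10.0
    max_length: float = 500.0
    extents: GateExtents = field(default_factory=GateExtents)
    not_config: NotTemplateConfig = field(default_factory=NotTemplateConfig)
    not_templates: tuple[str, ...] = ("coronal_pair", "fornix_crus_pair")
    weighting: str = "point"
    icc_variant: str = "agreement"
    phantom_bilateral: bool = False
    phantom_distractors: str = "default"

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        doc["extents"] = GateExtents(**doc.get("extents", {}))
        doc["not_config"] = NotTemplateConfig(**doc.get("not_config", {}))
        if "not_templates" in doc:
            doc["not_templates"] = tuple(doc["not_templates"])
        return cls(**doc)

    def tracking_params(self):
        from .tracking import TrackingParams

        low = TrackingParams(
            step_size=self.low_step, angle_threshold=self.low_angle,
            fod_threshold=self.fod_threshold, min_length=self.min_length,
            max_length=self.max_length,
            rng_seed=substream(self.seed, SUBSTREAM_TRACKING_LOW),
            preset="low_fidelity",
        )
        high = TrackingParams(
            step_size=self.high_step, angle_threshold=self.high_angle,
            fod_threshold=self.fod_threshold, min_length=self.min_length,
            max_length=self.max_length,
            rng_seed=substream(self.seed, SUBSTREAM_TRACKING_HIGH),
            preset="high_fidelity",
        )
        return low, high
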