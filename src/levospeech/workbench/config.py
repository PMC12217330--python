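"""Declarative pipeline configuration.

A single config object carries the tunables of every stage; each run's
resolved config (and its hash) is echoed to the log and embedded in output
artifacts so results are traceable to the exact settings that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import yaml

from levospeech.acoustics import AcousticConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline tunables with validated defaults."""

    acoustic: AcousticConfig = field(default_factory=AcousticConfig)
    shapiro_alpha: float = 0.05
    holm_correction: bool = True
    importance_method: str = "pmvd"
    max_exact_p: int = 12
    classification_threshold: float = 0.5
    nested_selection: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.shapiro_alpha < 1:
            raise ValueError("shapiro_alpha must be in (0, 1)")
        if self.importance_method not in ("pmvd", "lmg"):
            raise ValueError("importance_method must be 'pmvd' or 'lmg'")
        if not 0 < self.classification_threshold < 1:
            raise ValueError("classification_threshold must be in (0, 1)")
        if self.max_exact_p < 1:
            raise ValueError("max_exact_p must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        acoustic = AcousticConfig(**raw.pop("acoustic", {}))
        cfg = cls(acoustic=acoustic, **raw)
        logger.info("loaded config %s (hash %s)", path, cfg.hash())
        return cfg
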