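"""Validated YAML configuration shared by the CLI commands.

One global seed fans out deterministically to per-module seeds; every run
logs a hash of the fully resolved configuration so results are traceable to
the exact settings that produced them.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .features import ScoreConfig
from .grading import GradeThresholds
from .synthetic import DEFAULT_THRESHOLDS, GeneratorConfig

__all__ = ["PipelineConfig", "load_config"]

_KNOWN_KEYS = {
    "seed", "weights", "thresholds", "generator", "views", "policy",
    "detector_backend", "rules_file", "n_seedlings",
}


@dataclass
class PipelineConfig:
    seed: int = 42
    weights: tuple[float, ...] = (1.0,) * 7
    thresholds: GradeThresholds = DEFAULT_THRESHOLDS
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    views: tuple[int, ...] = (0, 45, 90, 135, 180, 225, 270, 315)
    policy: str = "worse_of"
    detector_backend: str = "oracle"  # oracle | yolo-txt
    rules_file: str | None = None
    n_seedlings: int = 200

    def score_config(self) -> ScoreConfig:
        return ScoreConfig(weights=self.weights)

    def module_seed(self, module: str) -> int:
        """Deterministic per-module seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{module}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def config_hash(self) -> str:
        payload = json.dumps(_serializable(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _serializable(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["thresholds"] = {"T_A": cfg.thresholds.T_A, "T_C": cfg.thresholds.T_C}
    return d


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config; None yields the defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; known: {sorted(_KNOWN_KEYS)}"
        )
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "weights" in raw:
        kwargs["weights"] = tuple(float(w) for w in raw["weights"])
    if "thresholds" in raw:
        th = raw["thresholds"]
        kwargs["thresholds"] = GradeThresholds(float(th["T_A"]), float(th["T_C"]))
    if "generator" in raw:
        gen = dict(raw["generator"])
        for key in ("defect_count_distribution", "root_distribution"):
            if key in gen:
                gen[key] = (gen[key][0], dict(gen[key][1]))
        if "view_span_distribution" in gen:
            gen["view_span_distribution"] = {
                int(k): float(v) for k, v in gen["view_span_distribution"].items()
            }
        if "category_prevalence" in gen:
            gen["category_prevalence"] = tuple(gen["category_prevalence"])
        kwargs["generator"] = GeneratorConfig(**gen)
    for key in ("views",):
        if key in raw:
            kwargs[key] = tuple(int(v) for v in raw[key])
    for key in ("policy", "detector_backend", "rules_file"):
        if key in raw:
            kwargs[key] = raw[key]
    if "n_seedlings" in raw:
        kwargs["n_seedlings"] = int(raw["n_seedlings"])
    cfg = PipelineConfig(**kwargs)
    if "seed" in kwargs and "generator" not in kwargs:
        # fan the global seed out to the generator
        cfg.generator = GeneratorConfig(seed=cfg.module_seed("generator"))
    return cfg
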