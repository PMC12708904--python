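"""Structured text configuration for the end-to-end pipeline.

The on-disk format is YAML with one section per stage::

    seed: 42
    output_dir: out
    log_level: INFO
    generator:        { n_records: 1100, ... }     # GeneratorConfig fields
    sentiment:        { alpha_s: 0.02, ... }       # SentimentParams fields
    lifecycle:        { thresholds: [0.1, 0.7, 0.2] }
    scenario_engine:  { beta0: 0.88, ... }         # ScenarioEngineConfig fields
    scenarios:        [ { name: baseline }, ... ]  # ScenarioSpec entries

Any omitted section falls back to the package defaults, which encode the
published study conditions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import ScenarioEngineConfig, ScenarioSpec, default_scenarios
from .errors import ConfigurationError
from .records import SentimentCategory
from .synthetic import GeneratorConfig
from .text_analytics import SentimentParams

__all__ = ["PipelineConfig", "load_config"]

_LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


def _build(cls, section: dict, what: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigurationError(f"unknown {what} keys: {', '.join(sorted(unknown))}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid {what} section: {exc}") from exc


def _coerce_generator(section: dict) -> dict:
    section = dict(section)
    for key in ("topic_mixture", "sentiment_mixture", "stage_mixture", "tier_mixture",
                "behavior_mixture", "stage_trust_means", "stage_rumor_means", "hijack_range"):
        if key in section:
            section[key] = tuple(section[key])
    for key in ("feature_rates", "score_targets"):
        if key in section:
            section[key] = {SentimentCategory(k): (tuple(v) if isinstance(v, (list, tuple)) else v)
                            for k, v in section[key].items()}
    if "sentiment_params" in section and isinstance(section["sentiment_params"], dict):
        section["sentiment_params"] = _build(SentimentParams, _coerce_sentiment(section["sentiment_params"]), "sentiment")
    return section


def _coerce_sentiment(section: dict) -> dict:
    section = dict(section)
    if "category_cuts" in section:
        section["category_cuts"] = tuple(section["category_cuts"])
    return section


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    sentiment: SentimentParams = field(default_factory=SentimentParams)
    lifecycle_thresholds: tuple[float, float, float] = (0.1, 0.7, 0.2)
    scenario_engine: ScenarioEngineConfig = field(default_factory=ScenarioEngineConfig)
    scenarios: tuple[ScenarioSpec, ...] = field(default_factory=lambda: tuple(default_scenarios()))
    output_dir: str = "rumordyn-out"
    seed: int = 0
    log_level: str = "INFO"
    raw_text: str | None = None

    def __post_init__(self) -> None:
        th = self.lifecycle_thresholds
        if len(th) != 3 or any(not 0.0 < x < 1.0 for x in th):
            raise ConfigurationError("lifecycle thresholds must be three reals in (0, 1)")
        if th[1] <= th[2]:
            raise ConfigurationError("decline threshold must exceed dissipation threshold")
        if self.log_level not in _LOG_LEVELS:
            raise ConfigurationError(f"log_level must be one of {_LOG_LEVELS}")

    @classmethod
    def from_dict(cls, data: dict, raw_text: str | None = None) -> "PipelineConfig":
        data = dict(data or {})
        known = {"generator", "sentiment", "lifecycle", "scenario_engine", "scenarios",
                 "output_dir", "seed", "log_level"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config sections: {', '.join(sorted(unknown))}")
        seed = int(data.get("seed", 0))
        gen_section = _coerce_generator(data.get("generator", {}))
        gen_section.setdefault("seed", seed)
        generator = _build(GeneratorConfig, gen_section, "generator")
        sentiment = _build(SentimentParams, _coerce_sentiment(data.get("sentiment", {})), "sentiment")
        lc = data.get("lifecycle", {})
        thresholds = tuple(lc.get("thresholds", (0.1, 0.7, 0.2)))
        engine = _build(ScenarioEngineConfig, dict(data.get("scenario_engine", {})), "scenario_engine")
        if "scenarios" in data:
            scenarios = tuple(_build(ScenarioSpec, dict(s), "scenario") for s in data["scenarios"])
        else:
            scenarios = tuple(default_scenarios())
        return cls(
            generator=generator,
            sentiment=sentiment,
            lifecycle_thresholds=thresholds,
            scenario_engine=engine,
            scenarios=scenarios,
            output_dir=str(data.get("output_dir", "rumordyn-out")),
            seed=seed,
            log_level=str(data.get("log_level", "INFO")),
            raw_text=raw_text,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        try:
            data = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config file {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(data, raw_text=text)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed, generator=self.generator.with_(seed=seed)
        )


def load_config(path: str | Path | None, seed: int | None = None) -> PipelineConfig:
    """Load a pipeline config file, or the defaults when ``path`` is None;
    an explicit ``seed`` overrides the file's."""
    cfg = PipelineConfig.from_yaml(path) if path is not None else PipelineConfig.from_dict({})
    if seed is not None:
        cfg = cfg.with_seed(seed)
    return cfg
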