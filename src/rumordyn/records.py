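"""Rumor-refutation event records and their on-disk formats.

A :class:`RefutationRecord` is one synthetic rumor-refutation event on a
microblogging platform: when it happened (abstract day index), who debunked
(source tier), where in the propagation cycle it sits (stage), what it was
about (topic), its text features (keyword counts plus a base polarity in
[0, 1]), and per-event trust/rumor/network quantities.

Corpora are stored as JSONL (one record per line) or CSV with identical
field names, and converted losslessly to/from a pandas DataFrame for
vectorised analysis.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .errors import InputError


class SourceTier(str, enum.Enum):
    """Hierarchical level of the debunking actor."""

    national = "national"
    provincial = "provincial"
    grassroots = "grassroots"


class Stage(str, enum.Enum):
    """Propagation stage of the rumor at refutation time."""

    early = "early"
    mid = "mid"
    late = "late"


class SentimentCategory(str, enum.Enum):
    """Five-level sentiment class of the public reaction."""

    strong_negative = "strong_negative"
    negative = "negative"
    neutral = "neutral"
    positive = "positive"
    strong_positive = "strong_positive"


class Behavior(str, enum.Enum):
    """Audience attitude x forwarding typology."""

    believe_forward = "believe_forward"
    disbelieve_forward = "disbelieve_forward"
    believe_noforward = "believe_noforward"
    disbelieve_noforward = "disbelieve_noforward"


SENTIMENT_ORDER = [
    SentimentCategory.strong_negative,
    SentimentCategory.negative,
    SentimentCategory.neutral,
    SentimentCategory.positive,
    SentimentCategory.strong_positive,
]

STAGE_ORDER = [Stage.early, Stage.mid, Stage.late]


@dataclass(slots=True)
class RefutationRecord:
    """One synthetic rumor-refutation event.

    Attributes
    ----------
    record_id:
        Unique identifier within a corpus.
    day:
        Day index >= 0; day 0 is the start of the refutation campaign.
    source_tier, stage, topic, sentiment_category, behavior:
        Categorical descriptors; ``topic`` is 1-based.
    base_polarity:
        Baseline sentiment polarity of the text in [0, 1] (an input
        feature; no NLP model is run in this package).
    n_pos, n_neg, n_panic, n_trust:
        Non-negative keyword-match counts from dictionary lookup.
    trust_level, rumor_level:
        Event-level trust and rumor intensity in [0, 1].
    hijack_index:
        Trust-hijack index >= 0 (degree of trust impersonation/exploitation).
    spread_intensity:
        Observed spread intensity >= 0.
    degree:
        Node degree of the posting account in the diffusion network.
    """

    record_id: str
    day: int
    source_tier: SourceTier
    stage: Stage
    topic: int
    sentiment_category: SentimentCategory
    base_polarity: float
    n_pos: int
    n_neg: int
    n_panic: int
    n_trust: int
    trust_level: float
    rumor_level: float
    hijack_index: float
    spread_intensity: float
    degree: int
    behavior: Behavior

    def __post_init__(self) -> None:
        if self.day < 0:
            raise InputError(f"day must be >= 0, got {self.day}")
        if self.topic < 1:
            raise InputError(f"topic is 1-based, got {self.topic}")
        for name in ("n_pos", "n_neg", "n_panic", "n_trust"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        for name in ("base_polarity", "trust_level", "rumor_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {v}")
        if self.hijack_index < 0 or self.spread_intensity < 0:
            raise InputError("hijack_index and spread_intensity must be >= 0")
        if self.degree < 1:
            raise InputError(f"degree must be a positive integer, got {self.degree}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("source_tier", "stage", "sentiment_category", "behavior"):
            d[key] = d[key].value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RefutationRecord":
        return cls(
            record_id=str(d["record_id"]),
            day=int(d["day"]),
            source_tier=SourceTier(d["source_tier"]),
            stage=Stage(d["stage"]),
            topic=int(d["topic"]),
            sentiment_category=SentimentCategory(d["sentiment_category"]),
            base_polarity=float(d["base_polarity"]),
            n_pos=int(d["n_pos"]),
            n_neg=int(d["n_neg"]),
            n_panic=int(d["n_panic"]),
            n_trust=int(d["n_trust"]),
            trust_level=float(d["trust_level"]),
            rumor_level=float(d["rumor_level"]),
            hijack_index=float(d["hijack_index"]),
            spread_intensity=float(d["spread_intensity"]),
            degree=int(d["degree"]),
            behavior=Behavior(d["behavior"]),
        )


Corpus = Sequence[RefutationRecord]
CorpusLike = Union[Corpus, pd.DataFrame]

FIELD_NAMES = [f.name for f in dataclasses.fields(RefutationRecord)]


def corpus_to_frame(records: CorpusLike) -> pd.DataFrame:
    """Return the corpus as a DataFrame with enum fields as plain strings."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.to_dict() for r in records], columns=FIELD_NAMES)


def frame_to_corpus(frame: pd.DataFrame) -> list[RefutationRecord]:
    return [RefutationRecord.from_dict(row) for row in frame.to_dict("records")]


def write_jsonl(records: CorpusLike, path: str | Path) -> None:
    frame = corpus_to_frame(records)
    with open(path, "w", encoding="utf-8") as fh:
        for row in frame.to_dict("records"):
            fh.write(json.dumps(row, sort_keys=False) + "\n")


def read_jsonl(path: str | Path) -> list[RefutationRecord]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(RefutationRecord.from_dict(json.loads(line)))
    return out


def write_csv(records: CorpusLike, path: str | Path) -> None:
    # .17g round-trips doubles exactly; the pandas default truncates.
    corpus_to_frame(records).to_csv(path, index=False, float_format=lambda v: format(v, ".17g"))


def read_csv(path: str | Path) -> list[RefutationRecord]:
    return frame_to_corpus(pd.read_csv(path, float_precision="round_trip"))


def iter_records(records: CorpusLike) -> Iterable[RefutationRecord]:
    if isinstance(records, pd.DataFrame):
        return iter(frame_to_corpus(records))
    return iter(records)
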