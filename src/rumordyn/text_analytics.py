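"""Text-derived statistics: smoothed topic-word probabilities, source-topic
conditionals, keyword-weighted sentiment scoring, token rankings, and
stage-topic clustering.

The topic-word estimator operates on *given* count matrices — no topic-model
inference is run here — and applies prior-count smoothing:

    P(word_i | topic_k) = (beta_{k,i} + n_{k,i}) / sum_j (beta_{k,j} + n_{k,j})

The sentiment score combines a base polarity in [0, 1] with keyword-count
adjustments:

    S_final = ((S_base + alpha * (N_pos - N_neg)) + adj_panic + adj_trust - 0.5) * 2

and is described as ranging over (0, 2) with higher = more positive.  Note
that the raw formula does not itself enforce that range (with all
adjustments zero it maps [0, 1] onto [-1, 1]); clamping to [0, 2] is
therefore applied by default but is an explicit, documented choice
(``SentimentParams.clamp``), not a silent correction.  Panic keywords
lower and trust keywords raise the score; both weights are configurable,
including their sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ConfigurationError, InputError, UndefinedConditionalError
from .records import CorpusLike, SentimentCategory, SENTIMENT_ORDER, corpus_to_frame

__all__ = [
    "TopicWordCounts",
    "SentimentParams",
    "ScoredText",
    "topic_word_prob",
    "topic_word_distribution",
    "source_topic_prob",
    "sentiment_score",
    "classify_corpus_sentiment",
    "topic_shares",
    "top_k_word_frequencies",
    "stage_topic_clustering",
    "ClusteringResult",
]


@dataclass(frozen=True)
class TopicWordCounts:
    """Observed word counts ``n[k, i]`` and prior counts ``beta[k, i]`` for
    K topics over a vocabulary of V words."""

    counts: np.ndarray
    priors: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        priors = np.asarray(self.priors, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "priors", priors)
        if counts.ndim != 2 or priors.shape != counts.shape:
            raise InputError("counts and priors must be 2-D arrays of equal shape")
        if np.any(counts < 0):
            raise InputError("counts must be non-negative")
        if np.any(priors <= 0):
            raise InputError("priors must be strictly positive")

    @property
    def K(self) -> int:
        return self.counts.shape[0]

    @property
    def V(self) -> int:
        return self.counts.shape[1]


def topic_word_distribution(tw: TopicWordCounts, topic: int) -> np.ndarray:
    """Smoothed word distribution of one topic; sums to 1."""
    if not 0 <= topic < tw.K:
        raise InputError(f"topic index {topic} out of range [0, {tw.K})")
    row = tw.priors[topic] + tw.counts[topic]
    return row / row.sum()


def topic_word_prob(tw: TopicWordCounts, word: int, topic: int) -> float:
    """Smoothed probability of generating ``word`` under ``topic``."""
    if not 0 <= word < tw.V:
        raise InputError(f"word index {word} out of range [0, {tw.V})")
    return float(topic_word_distribution(tw, topic)[word])


def source_topic_prob(records: Sequence[tuple], source, topic) -> float:
    """Conditional probability of ``source`` given ``topic`` by direct counting.

    ``records`` is a sequence of ``(source, topic)`` pairs.  Requesting a
    topic never observed raises :class:`UndefinedConditionalError` — the
    conditional is undefined, not zero.
    """
    n_topic = sum(1 for _, t in records if t == topic)
    if n_topic == 0:
        raise UndefinedConditionalError(f"no record with topic {topic!r}; P(source | topic) undefined")
    n_joint = sum(1 for s, t in records if t == topic and s == source)
    return n_joint / n_topic


@dataclass(frozen=True)
class SentimentParams:
    """Weights and binning of the keyword-adjusted sentiment score.

    ``alpha_s`` weights the positive/negative keyword imbalance;
    ``w_panic`` and ``w_trust`` convert panic/trust keyword counts into
    per-document adjustments (panic subtracts, trust adds).  The five
    categories partition [0, 2] at ``category_cuts`` (default: an even
    partition, since no published boundaries exist).
    """

    alpha_s: float = 0.02
    w_panic: float = 0.02
    w_trust: float = 0.02
    clamp: bool = True
    category_cuts: tuple[float, float, float, float] = (0.4, 0.8, 1.2, 1.6)

    def __post_init__(self) -> None:
        cuts = self.category_cuts
        if len(cuts) != 4 or any(cuts[i] >= cuts[i + 1] for i in range(3)):
            raise ConfigurationError("category_cuts must be 4 strictly increasing reals")
        if not (0.0 < cuts[0] and cuts[-1] < 2.0):
            raise ConfigurationError("category_cuts must lie strictly inside (0, 2)")
        if self.alpha_s < 0:
            raise ConfigurationError("alpha_s must be >= 0")


@dataclass(frozen=True)
class ScoredText:
    """A scored document: inputs, raw adjustments, final score and category."""

    s_base: float
    n_pos: int
    n_neg: int
    panic_adj: float
    trust_adj: float
    s_final: float
    category: SentimentCategory


def _categorize(scores: np.ndarray, cuts: Sequence[float]) -> np.ndarray:
    return np.searchsorted(np.asarray(cuts, dtype=float), scores, side="left")


def sentiment_score(
    s_base: float,
    n_pos: int,
    n_neg: int,
    panic_adj: float,
    trust_adj: float,
    params: SentimentParams = SentimentParams(),
) -> ScoredText:
    """Score one document with the keyword-adjusted sentiment formula."""
    if not 0.0 <= s_base <= 1.0:
        raise InputError(f"s_base must lie in [0, 1], got {s_base}")
    if n_pos < 0 or n_neg < 0:
        raise InputError("keyword counts must be >= 0")
    raw = ((s_base + params.alpha_s * (n_pos - n_neg)) + panic_adj + trust_adj - 0.5) * 2.0
    s_final = float(np.clip(raw, 0.0, 2.0)) if params.clamp else float(raw)
    cat = SENTIMENT_ORDER[int(_categorize(np.array([s_final]), params.category_cuts)[0])]
    return ScoredText(
        s_base=float(s_base),
        n_pos=int(n_pos),
        n_neg=int(n_neg),
        panic_adj=float(panic_adj),
        trust_adj=float(trust_adj),
        s_final=s_final,
        category=cat,
    )


def classify_corpus_sentiment(
    records: CorpusLike, params: SentimentParams = SentimentParams()
) -> pd.Series:
    """Score every record from its stored feature counts and return the
    five-category share vector (sums to 1).

    Per record, the panic adjustment is ``-w_panic * n_panic`` and the
    trust adjustment ``+w_trust * n_trust``.
    """
    frame = corpus_to_frame(records)
    if len(frame) == 0:
        raise InputError("empty corpus")
    raw = (
        frame["base_polarity"].to_numpy(dtype=float)
        + params.alpha_s * (frame["n_pos"].to_numpy(dtype=float) - frame["n_neg"].to_numpy(dtype=float))
        - params.w_panic * frame["n_panic"].to_numpy(dtype=float)
        + params.w_trust * frame["n_trust"].to_numpy(dtype=float)
        - 0.5
    ) * 2.0
    scores = np.clip(raw, 0.0, 2.0) if params.clamp else raw
    idx = _categorize(scores, params.category_cuts)
    shares = np.bincount(idx, minlength=5) / len(frame)
    return pd.Series(shares, index=[c.value for c in SENTIMENT_ORDER], name="share")


def topic_shares(records: CorpusLike, k_topics: int | None = None) -> pd.Series:
    """Empirical topic share vector of a corpus (sums to 1)."""
    frame = corpus_to_frame(records)
    if len(frame) == 0:
        raise InputError("empty corpus")
    topics = frame["topic"].to_numpy(dtype=int)
    k = int(k_topics if k_topics is not None else topics.max())
    counts = np.bincount(topics, minlength=k + 1)[1:]
    return pd.Series(counts / counts.sum(), index=range(1, k + 1), name="share")


def top_k_word_frequencies(counts: Mapping[str, int] | pd.Series, k: int) -> list[tuple[str, int]]:
    """Top-k tokens by count, descending; ties broken lexicographically."""
    if k < 1:
        raise InputError("k must be >= 1")
    items = counts.items() if hasattr(counts, "items") else iter(counts)
    ranked = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    return [(tok, int(c)) for tok, c in ranked[:k]]


@dataclass(frozen=True)
class ClusteringResult:
    """2-D principal-axis projection and cluster labels of documents."""

    coords: np.ndarray
    labels: np.ndarray
    stages: tuple
    explained_variance_ratio: tuple[float, float]
    n_effective_clusters: int


def stage_topic_clustering(
    doc_topic: np.ndarray,
    stages: Sequence,
    n_clusters: int = 3,
    seed: int = 0,
) -> ClusteringResult:
    """Project document topic-share vectors onto the top-2 principal axes
    and partition them into ``n_clusters`` seeded-k-means clusters.

    The projection uses the deterministic sign convention that each axis's
    largest-magnitude loading is positive.  Identical documents collapse
    into a single effective cluster, which is reported, not an error.
    """
    X = np.asarray(doc_topic, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise InputError("need a 2-D array with at least 3 documents")
    if X.shape[0] < n_clusters:
        raise InputError(f"fewer documents ({X.shape[0]}) than clusters ({n_clusters})")
    if len(stages) != X.shape[0]:
        raise InputError("stages must have one label per document")
    if not np.allclose(X.sum(axis=1), 1.0, atol=1e-6):
        raise InputError("each document's topic shares must sum to 1")

    n_comp = min(2, X.shape[1], X.shape[0])
    pca = PCA(n_components=n_comp, svd_solver="full")  # svd_flip gives the sign rule
    coords = pca.fit_transform(X)
    if n_comp < 2:  # degenerate vocabulary: pad the second axis with zeros
        coords = np.hstack([coords, np.zeros((X.shape[0], 2 - n_comp))])
    evr = tuple(float(v) for v in pca.explained_variance_ratio_[:2]) + (0.0, 0.0)

    if np.ptp(coords, axis=0).max() < 1e-12:
        # all documents identical: one effective cluster, the rest empty
        labels = np.zeros(X.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # near-duplicate points trigger a convergence warning
            labels = km.fit_predict(coords)
    return ClusteringResult(
        coords=coords,
        labels=labels,
        stages=tuple(stages),
        explained_variance_ratio=(evr[0], evr[1]),
        n_effective_clusters=int(np.unique(labels).size),
    )
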