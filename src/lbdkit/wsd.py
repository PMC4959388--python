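"""Sense-assignment backends: random, noisy oracle, sense-collapsing,
personalized PageRank over a concept graph, and sense-centroid VSM.

Every backend maps each :class:`~lbdkit.corpus.TermMention` of a document to
one of its candidate concepts, or abstains. All stochastic backends take an
explicit seed; there is no global randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
from scipy import sparse

from .corpus import (
    AnnotatedDocument,
    Assignment,
    ConceptGraph,
    Document,
    GoldSenseAnnotation,
    SenseInventory,
    TermMention,
    match_terms,
    normalize,
    tokenize,
)

__all__ = [
    "DEFAULT_STOPWORDS",
    "PersonalizationVector",
    "RankVector",
    "FeatureVector",
    "SenseCentroid",
    "WsdBackend",
    "RandomBackend",
    "OracleBackend",
    "CollapseBackend",
    "PPRBackend",
    "VSMBackend",
    "personalized_pagerank",
    "disambiguate_random",
    "disambiguate_oracle",
    "disambiguate_ppr",
    "disambiguate_vsm",
    "extract_features",
    "train_centroids",
    "generate_pseudo_labels",
    "annotate_corpus",
    "cosine_similarity",
]

#: Small default stoplist used to pick out "content words" for VSM features.
DEFAULT_STOPWORDS = frozenset(
    """a an the and or but nor of in on at to from by for with without about as
    is are was were be been being has have had do does did will would can
    could shall should may might must this that these those it its their his
    her our your my not no than then so such via per if when while which who
    whom whose what where into over under between during each""".split()
)


@dataclass(frozen=True)
class PersonalizationVector:
    """Teleport distribution over graph nodes; weights sum to 1."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.weights:
            total = sum(self.weights.values())
            if any(w < 0 for w in self.weights.values()):
                raise ValueError("personalization weights must be non-negative")
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"personalization weights must sum to 1, got {total}")

    @classmethod
    def uniform(cls, cuis: Iterable[str]) -> "PersonalizationVector":
        cuis = sorted(set(cuis))
        if not cuis:
            return cls(weights={})
        w = 1.0 / len(cuis)
        return cls(weights={c: w for c in cuis})


@dataclass(frozen=True)
class RankVector:
    """Stationary scores from personalized PageRank; sums to 1 ± tolerance."""

    scores: Mapping[str, float]

    def __getitem__(self, cui: str) -> float:
        return self.scores.get(cui, 0.0)


@dataclass(frozen=True)
class FeatureVector:
    features: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.features.values()):
            raise ValueError("feature weights must be non-negative")

    def norm(self) -> float:
        return math.sqrt(sum(v * v for v in self.features.values()))


@dataclass(frozen=True)
class SenseCentroid:
    cui: str
    vector: Mapping[str, float]
    support: int

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("centroid support must be >= 1")
        if not self.vector:
            raise ValueError("centroid vector must be non-empty")


def cosine_similarity(a: Mapping[str, float], b: Mapping[str, float]) -> float:
    """Cosine of two sparse vectors; 0.0 if either has zero norm."""
    if len(a) > len(b):
        a, b = b, a
    dot = sum(v * b.get(k, 0.0) for k, v in a.items())
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return dot / (na * nb)


# ---------------------------------------------------------------------------
# personalized PageRank
# ---------------------------------------------------------------------------


def personalized_pagerank(
    graph: ConceptGraph,
    personalization: PersonalizationVector | Mapping[str, float],
    damping: float = 0.85,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> RankVector:
    """Rank graph nodes by the fixed point of r = d·M·r + (1−d)·p.

    M is the column-stochastic transition matrix over the undirected edges
    (multi-edges collapse to their multiplicity as weight); mass on dangling
    nodes is redistributed according to the personalization vector p.
    Iteration stops when the L1 change falls below *tol* or after
    *max_iter* sweeps.
    """
    if isinstance(personalization, PersonalizationVector):
        p_weights = dict(personalization.weights)
    else:
        p_weights = dict(personalization)
    if len(graph) == 0:
        raise ValueError("personalized_pagerank: graph is empty")
    if not p_weights:
        raise ValueError("personalized_pagerank: personalization is empty")
    unknown = [c for c in p_weights if c not in graph]
    if unknown:
        raise ValueError(f"personalization concepts not in graph: {sorted(unknown)[:5]}")
    if not 0.0 <= damping < 1.0:
        raise ValueError(f"damping must be in [0, 1), got {damping}")

    nodes = sorted(graph.nodes)
    index = {c: i for i, c in enumerate(nodes)}
    n = len(nodes)

    rows, cols, vals = [], [], []
    for u, v, w in graph.edges():
        rows.extend((index[u], index[v]))
        cols.extend((index[v], index[u]))
        vals.extend((w, w))
    W = sparse.csr_array((vals, (rows, cols)), shape=(n, n), dtype=float)
    out_weight = np.asarray(W.sum(axis=0)).ravel()
    dangling = out_weight == 0
    inv_out = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, out_weight))
    M = W @ sparse.diags_array(inv_out)

    p = np.zeros(n)
    total = sum(p_weights.values())
    for cui, w in p_weights.items():
        p[index[cui]] = w / total
    r = p.copy()
    for _ in range(max_iter):
        dangling_mass = r[dangling].sum()
        r_new = damping * (M @ r + dangling_mass * p) + (1.0 - damping) * p
        if np.abs(r_new - r).sum() < tol:
            r = r_new
            break
        r = r_new
    r /= r.sum()
    return RankVector(scores={c: float(r[index[c]]) for c in nodes})


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------


class WsdBackend(Protocol):
    def annotate(self, doc: Document, mentions: Sequence[TermMention]) -> AnnotatedDocument:
        ...


class RandomBackend:
    """Uniform random choice among each mention's candidates."""

    def __init__(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def annotate(self, doc: Document, mentions: Sequence[TermMention]) -> AnnotatedDocument:
        assignments = []
        for m in mentions:
            cuis = m.candidate_cuis
            chosen = cuis[0] if len(cuis) == 1 else cuis[self._rng.integers(len(cuis))]
            assignments.append(Assignment(mention=m, cui=chosen))
        return AnnotatedDocument(doc_id=doc.doc_id, year=doc.year, assignments=assignments)


class OracleBackend:
    """Noisy oracle: assigns gold with probability *target_accuracy*,
    otherwise a uniformly chosen wrong candidate. Monosemous mentions are
    always correct. Stands in for WSD systems of arbitrary accuracy."""

    def __init__(
        self,
        gold: Iterable[GoldSenseAnnotation],
        target_accuracy: float,
        seed: int,
    ) -> None:
        if not 0.0 <= target_accuracy <= 1.0:
            raise ValueError(f"target_accuracy must be in [0, 1], got {target_accuracy}")
        self._gold = {g.key: g.gold_cui for g in gold}
        self._accuracy = target_accuracy
        self._rng = np.random.default_rng(seed)

    def annotate(self, doc: Document, mentions: Sequence[TermMention]) -> AnnotatedDocument:
        assignments = []
        for m in mentions:
            cuis = m.candidate_cuis
            if len(cuis) == 1:
                assignments.append(Assignment(mention=m, cui=cuis[0]))
                continue
            gold_cui = self._gold.get((m.doc_id, m.start, m.end))
            if gold_cui is None:
                raise ValueError(
                    f"no gold annotation for ambiguous mention {m.surface!r} "
                    f"in {m.doc_id} at {m.span}"
                )
            if self._rng.random() < self._accuracy:
                chosen = gold_cui
            else:
                wrong = [c for c in cuis if c != gold_cui]
                chosen = wrong[self._rng.integers(len(wrong))] if wrong else gold_cui
            assignments.append(Assignment(mention=m, cui=chosen))
        return AnnotatedDocument(doc_id=doc.doc_id, year=doc.year, assignments=assignments)


class CollapseBackend:
    """Sense-collapsing baseline: every mention of a term gets the same sense
    (the lexicographically smallest candidate cui), modelling a system that
    ignores ambiguity altogether."""

    def annotate(self, doc: Document, mentions: Sequence[TermMention]) -> AnnotatedDocument:
        assignments = [Assignment(mention=m, cui=min(m.candidate_cuis)) for m in mentions]
        return AnnotatedDocument(doc_id=doc.doc_id, year=doc.year, assignments=assignments)


class PPRBackend:
    """Graph WSD by personalized PageRank.

    Default single-pass mode runs one PPR per document with the teleport
    distribution uniform over all candidate concepts of all mentions in the
    document, then assigns each mention its highest-ranked candidate (ties
    broken by lexicographically smallest cui). The per-target mode runs one
    PPR per ambiguous mention, with the target's own candidates removed from
    the personalization.
    """

    def __init__(
        self,
        graph: ConceptGraph,
        damping: float = 0.85,
        max_iter: int = 200,
        tol: float = 1e-9,
        mode: str = "single_pass",
    ) -> None:
        if mode not in ("single_pass", "per_target"):
            raise ValueError(f"unknown PPR mode {mode!r}")
        self._graph = graph
        self._damping = damping
        self._max_iter = max_iter
        self._tol = tol
        self._mode = mode

    def _rank(self, cuis: Iterable[str]) -> RankVector | None:
        p = PersonalizationVector.uniform(c for c in cuis if c in self._graph)
        if not p.weights:
            return None
        return personalized_pagerank(
            self._graph, p, damping=self._damping, max_iter=self._max_iter, tol=self._tol
        )

    def annotate(self, doc: Document, mentions: Sequence[TermMention]) -> AnnotatedDocument:
        if self._mode == "single_pass":
            return self._annotate_single_pass(doc, mentions)
        return self._annotate_per_target(doc, mentions)

    def _pick(self, mention: TermMention, ranks: RankVector | None) -> str | None:
        in_graph = [c for c in mention.candidate_cuis if c in self._graph]
        if not in_graph:
            return None
        if ranks is None:
            return min(in_graph)
        # argmax with ties broken by lexicographically smallest cui
        top = max(ranks[c] for c in in_graph)
        return min(c for c in in_graph if ranks[c] == top)

    def _annotate_single_pass(
        self, doc: Document, mentions: Sequence[TermMention]
    ) -> AnnotatedDocument:
        all_cuis = {c for m in mentions for c in m.candidate_cuis}
        ranks = self._rank(all_cuis)
        assignments = []
        for m in mentions:
            if len(m.candidate_cuis) == 1:
                assignments.append(Assignment(mention=m, cui=m.candidate_cuis[0]))
                continue
            chosen = self._pick(m, ranks)
            if chosen is not None and len(mentions) == 1:
                # lone ambiguous mention with no edges carries no signal
                if all(self._graph.degree(c) == 0 for c in m.candidate_cuis if c in self._graph):
                    chosen = None
            assignments.append(Assignment(mention=m, cui=chosen))
        return AnnotatedDocument(doc_id=doc.doc_id, year=doc.year, assignments=assignments)

    def _annotate_per_target(
        self, doc: Document, mentions: Sequence[TermMention]
    ) -> AnnotatedDocument:
        assignments = []
        for m in mentions:
            if len(m.candidate_cuis) == 1:
                assignments.append(Assignment(mention=m, cui=m.candidate_cuis[0]))
                continue
            context = {
                c
                for other in mentions
                if other is not m
                for c in other.candidate_cuis
                if c not in m.candidate_cuis
            }
            ranks = self._rank(context)
            chosen = self._pick(m, ranks) if ranks is not None else None
            assignments.append(Assignment(mention=m, cui=chosen))
        return AnnotatedDocument(doc_id=doc.doc_id, year=doc.year, assignments=assignments)


class VSMBackend:
    """Sense-centroid vector space model: a mention is assigned the candidate
    whose centroid is most cosine-similar to the mention's feature vector."""

    def __init__(
        self,
        centroids: Mapping[str, SenseCentroid],
        window: int = 4,
        stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    ) -> None:
        self._centroids = dict(centroids)
        self._window = window
        self._stopwords = stopwords

    def annotate(self, doc: Document, mentions: Sequence[TermMention]) -> AnnotatedDocument:
        assignments = []
        for m in mentions:
            if len(m.candidate_cuis) == 1:
                assignments.append(Assignment(mention=m, cui=m.candidate_cuis[0]))
                continue
            fv = extract_features(doc, m, window=self._window, stopwords=self._stopwords)
            scored = [
                (cui, cosine_similarity(fv.features, self._centroids[cui].vector))
                for cui in m.candidate_cuis
                if cui in self._centroids
            ]
            if not scored or fv.norm() == 0.0:
                assignments.append(Assignment(mention=m, cui=None))
                continue
            top = max(s for _, s in scored)
            chosen = min(cui for cui, s in scored if s == top)
            assignments.append(Assignment(mention=m, cui=chosen))
        return AnnotatedDocument(doc_id=doc.doc_id, year=doc.year, assignments=assignments)


# ---------------------------------------------------------------------------
# VSM features and pseudo-labeled training data
# ---------------------------------------------------------------------------


def _sentence_token_ranges(raw_text: str) -> list[int]:
    """Cumulative token counts at sentence boundaries (period splitting)."""
    bounds = [0]
    for part in raw_text.split("."):
        bounds.append(bounds[-1] + len(normalize(part).split()))
    return bounds


def extract_features(
    doc: Document,
    mention: TermMention,
    window: int = 4,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    lemmatizer=None,
) -> FeatureVector:
    """Bag-of-lemmas features for a mention.

    Union of (a) non-stopword tokens of the mention's sentence and (b) all
    tokens within ±window tokens of the mention, with counts accumulated
    across the two sources. The mention's own tokens are excluded. The
    default lemmatizer is identity-after-normalization.
    """
    lemma = lemmatizer or (lambda t: t)
    raw = doc.field_text(mention.field)
    text = normalize(raw)
    tokens = tokenize(text)
    # token index range covered by the mention
    m_first = m_last = None
    for i, (_, start, end) in enumerate(tokens):
        if start >= mention.start and end <= mention.end:
            if m_first is None:
                m_first = i
            m_last = i
    if m_first is None or m_last is None:
        raise ValueError(f"mention span {mention.span} not found in {mention.doc_id}")

    counts: dict[str, float] = {}

    bounds = _sentence_token_ranges(raw)
    sent_start, sent_end = 0, len(tokens)
    for lo, hi in zip(bounds, bounds[1:]):
        if lo <= m_first < hi:
            sent_start, sent_end = lo, hi
            break
    for i in range(sent_start, sent_end):
        tok = tokens[i][0]
        if m_first <= i <= m_last or tok in stopwords:
            continue
        key = lemma(tok)
        counts[key] = counts.get(key, 0.0) + 1.0

    lo = max(0, m_first - window)
    hi = min(len(tokens), m_last + 1 + window)
    for i in range(lo, hi):
        if m_first <= i <= m_last:
            continue
        key = lemma(tokens[i][0])
        counts[key] = counts.get(key, 0.0) + 1.0

    return FeatureVector(features=counts)


def train_centroids(
    labeled: Sequence[tuple[FeatureVector, str]]
) -> dict[str, SenseCentroid]:
    """Per-cui arithmetic mean of instance feature vectors."""
    if not labeled:
        raise ValueError("train_centroids: empty training set")
    sums: dict[str, dict[str, float]] = {}
    supports: dict[str, int] = {}
    for fv, cui in labeled:
        acc = sums.setdefault(cui, {})
        for k, v in fv.features.items():
            acc[k] = acc.get(k, 0.0) + v
        supports[cui] = supports.get(cui, 0) + 1
    out = {}
    for cui, acc in sums.items():
        n = supports[cui]
        out[cui] = SenseCentroid(
            cui=cui, vector={k: v / n for k, v in acc.items()}, support=n
        )
    return out


def generate_pseudo_labels(
    corpus: Sequence[Document],
    inventory: SenseInventory,
    window: int = 4,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    field_name: str = "title",
) -> list[tuple[FeatureVector, str]]:
    """Monosemous-relative pseudo-labeling.

    Each mention of a monosemous term whose concept is also a candidate
    sense of some ambiguous term yields one training instance labeled with
    that concept; ambiguous mentions contribute nothing.
    """
    ambiguous_senses = {
        c.cui
        for term, cands in inventory.items()
        if len(cands) >= 2
        for c in cands
    }
    labeled: list[tuple[FeatureVector, str]] = []
    for doc in corpus:
        for m in match_terms(doc, inventory, field_name):
            if len(m.candidates) != 1:
                continue
            cui = m.candidates[0].cui
            if cui in ambiguous_senses:
                fv = extract_features(doc, m, window=window, stopwords=stopwords)
                labeled.append((fv, cui))
    return labeled


# ---------------------------------------------------------------------------
# functional wrappers and corpus driver
# ---------------------------------------------------------------------------


def disambiguate_random(
    doc: Document, mentions: Sequence[TermMention], seed: int
) -> AnnotatedDocument:
    return RandomBackend(seed).annotate(doc, mentions)


def disambiguate_oracle(
    doc: Document,
    mentions: Sequence[TermMention],
    gold: Iterable[GoldSenseAnnotation],
    target_accuracy: float,
    seed: int,
) -> AnnotatedDocument:
    return OracleBackend(gold, target_accuracy, seed).annotate(doc, mentions)


def disambiguate_ppr(
    doc: Document,
    mentions: Sequence[TermMention],
    graph: ConceptGraph,
    **kwargs,
) -> AnnotatedDocument:
    return PPRBackend(graph, **kwargs).annotate(doc, mentions)


def disambiguate_vsm(
    doc: Document,
    mentions: Sequence[TermMention],
    centroids: Mapping[str, SenseCentroid],
    **kwargs,
) -> AnnotatedDocument:
    return VSMBackend(centroids, **kwargs).annotate(doc, mentions)


def annotate_corpus(
    docs: Sequence[Document],
    inventory: SenseInventory,
    backend: WsdBackend,
    field_name: str = "title",
) -> list[AnnotatedDocument]:
    """Match terms in each document and resolve them with *backend*."""
    return [backend.annotate(doc, match_terms(doc, inventory, field_name)) for doc in docs]
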