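"""The A-B-C engine: concept co-occurrence matrix from annotated titles,
semantic-type filtering, matrix squaring, and hidden-knowledge extraction.

Hidden knowledge is the set of concept pairs that are indirectly connected
(nonzero in the matrix square) but never directly co-occur (zero in the
matrix itself).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.io import mmread, mmwrite

from .corpus import AnnotatedDocument

__all__ = [
    "ConceptPair",
    "CooccurrenceMatrix",
    "filter_concepts",
    "build_matrix",
    "square_matrix",
    "hidden_knowledge",
    "open_discovery",
    "write_hidden",
    "read_hidden",
]


@dataclass(frozen=True)
class ConceptPair:
    """Unordered concept pair, stored with cui_a < cui_b."""

    cui_a: str
    cui_b: str
    score: float = 0.0
    link_count: int = 0

    def __post_init__(self) -> None:
        if not self.cui_a < self.cui_b:
            raise ValueError(
                f"ConceptPair requires cui_a < cui_b, got ({self.cui_a!r}, {self.cui_b!r})"
            )

    @classmethod
    def make(cls, u: str, v: str, score: float = 0.0, link_count: int = 0) -> "ConceptPair":
        a, b = sorted((u, v))
        return cls(cui_a=a, cui_b=b, score=score, link_count=link_count)

    @property
    def key(self) -> tuple[str, str]:
        return (self.cui_a, self.cui_b)


@dataclass
class CooccurrenceMatrix:
    """Sparse symmetric concept×concept co-occurrence counts."""

    concepts: list[str]
    counts: sparse.csr_array

    def __post_init__(self) -> None:
        self._index = {c: i for i, c in enumerate(self.concepts)}

    def index_of(self, cui: str) -> int:
        return self._index[cui]

    def __contains__(self, cui: str) -> bool:
        return cui in self._index

    @property
    def nnz(self) -> int:
        return self.counts.nnz

    def save(self, matrix_path: str | Path, index_path: str | Path) -> None:
        """Persist as MatrixMarket coordinate format plus a concept index."""
        mmwrite(str(matrix_path), sparse.coo_array(self.counts))
        with open(index_path, "w", encoding="utf-8") as fh:
            for cui in self.concepts:
                fh.write(cui + "\n")

    @classmethod
    def load(cls, matrix_path: str | Path, index_path: str | Path) -> "CooccurrenceMatrix":
        counts = sparse.csr_array(mmread(str(matrix_path)))
        with open(index_path, encoding="utf-8") as fh:
            concepts = [line.strip() for line in fh if line.strip()]
        return cls(concepts=concepts, counts=counts)


def filter_concepts(
    concepts: Iterable[str],
    type_map: Mapping[str, set[str]],
    excluded_types: set[str],
) -> set[str]:
    """Concepts surviving the semantic-type filter.

    A concept is removed iff it has at least one recorded semantic type and
    *all* of its types are excluded; untyped concepts are retained.
    """
    retained = set()
    for cui in concepts:
        types = type_map.get(cui, set())
        if types and types <= excluded_types:
            continue
        retained.add(cui)
    return retained


def build_matrix(
    annotated: Sequence[AnnotatedDocument],
    type_map: Mapping[str, set[str]] | None = None,
    excluded_types: set[str] | None = None,
    year_range: tuple[int, int] | None = None,
    count_mode: str = "document",
) -> CooccurrenceMatrix:
    """Title co-occurrence matrix over assigned concepts.

    Concepts failing the semantic-type filter are dropped first. For each
    document within *year_range* (inclusive bounds), every unordered pair of
    distinct assigned concepts in its title increments the pair count. In
    the default ``document`` mode a pair counts once per document regardless
    of repeated mentions; ``mention`` mode counts every mention pair.
    ABSTAIN assignments contribute nothing.
    """
    if count_mode not in ("document", "mention"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    if year_range is not None:
        lo, hi = year_range
        if lo > hi:
            raise ValueError(f"empty year_range {year_range}")
    type_map = type_map or {}
    excluded_types = excluded_types or set()

    vocab: dict[str, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    removed_cache: dict[str, bool] = {}

    def keep(cui: str) -> bool:
        if cui not in removed_cache:
            types = type_map.get(cui, set())
            removed_cache[cui] = not (types and types <= excluded_types)
        return removed_cache[cui]

    for doc in annotated:
        if year_range is not None and not (lo <= doc.year <= hi):
            continue
        cuis = [c for c in doc.assigned_cuis() if keep(c)]
        if count_mode == "document":
            cuis = sorted(set(cuis))
        for idx, u in enumerate(cuis):
            for v in cuis[idx + 1:]:
                if u == v:
                    continue
                iu = vocab.setdefault(u, len(vocab))
                iv = vocab.setdefault(v, len(vocab))
                rows.extend((iu, iv))
                cols.extend((iv, iu))
                vals.extend((1, 1))

    concepts = sorted(vocab)
    order = np.array([vocab[c] for c in concepts], dtype=np.int64)
    remap = np.empty(len(concepts), dtype=np.int64)
    remap[order] = np.arange(len(concepts))
    n = len(concepts)
    if rows:
        counts = sparse.csr_array(
            (np.asarray(vals), (remap[np.asarray(rows)], remap[np.asarray(cols)])),
            shape=(n, n),
            dtype=np.int64,
        )
        counts.sum_duplicates()
        counts.setdiag(0)
        counts.eliminate_zeros()
    else:
        counts = sparse.csr_array((n, n), dtype=np.int64)
    return CooccurrenceMatrix(concepts=concepts, counts=counts)


def square_matrix(matrix: CooccurrenceMatrix) -> sparse.csr_array:
    """A², whose entries count weighted length-2 paths between concepts."""
    a = matrix.counts
    return sparse.csr_array(a @ a)


def hidden_knowledge(
    matrix: CooccurrenceMatrix, squared: sparse.csr_array | None = None
) -> list[ConceptPair]:
    """Pairs nonzero in A² but zero in A, in lexicographic order.

    score is the A² entry (weighted path count); link_count is the number
    of distinct linking concepts.
    """
    a = matrix.counts
    b = square_matrix(matrix) if squared is None else squared
    if b.shape != a.shape:
        raise ValueError("matrix and its square must share the concept index")
    binary = sparse.csr_array((a > 0).astype(np.int64))
    links = sparse.csr_array(binary @ binary)

    b_coo = sparse.coo_array(b)
    a_dok = sparse.dok_array(a)
    pairs = []
    for i, j, score in zip(b_coo.row, b_coo.col, b_coo.data):
        if i >= j or score == 0:
            continue
        if a_dok[i, j] != 0:
            continue
        pairs.append(
            ConceptPair(
                cui_a=matrix.concepts[i],
                cui_b=matrix.concepts[j],
                score=float(score),
                link_count=int(links[i, j]),
            )
        )
    pairs.sort(key=lambda p: p.key)
    return pairs


def open_discovery(
    matrix: CooccurrenceMatrix, source_cui: str, top_n: int = 0
) -> list[ConceptPair]:
    """Hidden pairs involving *source_cui*, by descending score (ties by cui).

    top_n = 0 returns all.
    """
    if source_cui not in matrix:
        raise ValueError(f"unknown source cui {source_cui!r}")
    involving = [
        p for p in hidden_knowledge(matrix) if source_cui in (p.cui_a, p.cui_b)
    ]
    involving.sort(key=lambda p: (-p.score, p.cui_a, p.cui_b))
    return involving[:top_n] if top_n else involving


def write_hidden(pairs: Iterable[ConceptPair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cui_a\tcui_b\tscore\tlink_count\n")
        for p in pairs:
            fh.write(f"{p.cui_a}\t{p.cui_b}\t{p.score:g}\t{p.link_count}\n")


def read_hidden(path: str | Path) -> list[ConceptPair]:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "cui_a\tcui_b\tscore\tlink_count":
            raise ValueError(f"{path}: unexpected hidden-knowledge header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            a, b, score, links = line.rstrip("\n").split("\t")
            pairs.append(
                ConceptPair(cui_a=a, cui_b=b, score=float(score), link_count=int(links))
            )
    return pairs
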