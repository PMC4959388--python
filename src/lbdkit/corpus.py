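"""Domain types and I/O for corpora, sense inventories, concept graphs and annotations.

The native corpus dialect is JSON Lines (one document per line); tabular
resources (inventory, semantic types, relations, gold senses) are
tab-separated text. A minimal PubMed XML reader is provided as a
convenience. All character offsets used by this package are 0-based,
half-open, and refer to the *normalized* field text.
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "ABSTAIN",
    "Concept",
    "Document",
    "SenseInventory",
    "TermMention",
    "Assignment",
    "AnnotatedDocument",
    "ConceptGraph",
    "GoldSenseAnnotation",
    "CorpusFormatError",
    "normalize",
    "tokenize",
    "match_terms",
    "read_corpus",
    "write_corpus",
    "read_inventory",
    "write_inventory",
    "read_semantic_types",
    "write_semantic_types",
    "read_relations",
    "write_relations",
    "read_gold",
    "write_gold",
    "read_annotations",
    "write_annotations",
]

#: Sentinel used in assignments when a backend declines to choose a sense.
ABSTAIN = None


class CorpusFormatError(ValueError):
    """Raised when an input file does not conform to its declared format."""


@dataclass(frozen=True)
class Concept:
    """A concept identifier (CUI-like) with description and semantic types."""

    cui: str
    description: str = ""
    semantic_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cui:
            raise ValueError("Concept cui must be non-empty")


@dataclass(frozen=True)
class Document:
    """A dated document; the title is the unit of co-occurrence."""

    doc_id: str
    title: str
    year: int
    abstract: str | None = None

    def __post_init__(self) -> None:
        if not self.title:
            raise ValueError(f"Document {self.doc_id!r}: title must be non-empty")

    def field_text(self, field_name: str) -> str:
        if field_name == "title":
            return self.title
        if field_name == "abstract":
            if self.abstract is None:
                raise ValueError(f"Document {self.doc_id!r} has no abstract")
            return self.abstract
        raise ValueError(f"unknown field {field_name!r}")


class SenseInventory:
    """Mapping from normalized surface term to its candidate concepts.

    Terms are normalized at construction time; duplicate term rows merge
    their concept sets (first occurrence order preserved). A term with two
    or more candidate concepts is *ambiguous*.
    """

    def __init__(self, entries: Mapping[str, Sequence[Concept]] | None = None) -> None:
        self._entries: dict[str, tuple[Concept, ...]] = {}
        self._max_tokens = 0
        if entries:
            for term, concepts in entries.items():
                for concept in concepts:
                    self.add(term, concept)

    def add(self, term: str, concept: Concept) -> None:
        key = normalize(term)
        if not key:
            raise ValueError(f"term {term!r} normalizes to the empty string")
        existing = self._entries.get(key, ())
        if all(c.cui != concept.cui for c in existing):
            self._entries[key] = existing + (concept,)
        self._max_tokens = max(self._max_tokens, len(key.split()))

    def lookup(self, term: str) -> tuple[Concept, ...]:
        """Candidate concepts for a (raw or normalized) term; () if absent."""
        return self._entries.get(normalize(term), ())

    def __contains__(self, term: str) -> bool:
        return normalize(term) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self._entries)

    @property
    def max_term_tokens(self) -> int:
        return self._max_tokens

    def is_ambiguous(self, term: str) -> bool:
        return len(self.lookup(term)) >= 2

    def ambiguous_terms(self) -> tuple[str, ...]:
        return tuple(t for t, cs in self._entries.items() if len(cs) >= 2)

    def monosemous_terms(self) -> tuple[str, ...]:
        return tuple(t for t, cs in self._entries.items() if len(cs) == 1)

    def concepts(self) -> dict[str, Concept]:
        """All distinct concepts in the inventory, keyed by cui."""
        out: dict[str, Concept] = {}
        for cands in self._entries.values():
            for c in cands:
                out.setdefault(c.cui, c)
        return out

    def items(self) -> Iterator[tuple[str, tuple[Concept, ...]]]:
        return iter(self._entries.items())


@dataclass(frozen=True)
class TermMention:
    """An inventory term matched in a document field.

    ``start``/``end`` are offsets into the normalized field text.
    """

    doc_id: str
    field: str
    start: int
    end: int
    surface: str
    candidates: tuple[Concept, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def candidate_cuis(self) -> tuple[str, ...]:
        return tuple(c.cui for c in self.candidates)

    def is_ambiguous(self) -> bool:
        return len(self.candidates) >= 2


@dataclass(frozen=True)
class Assignment:
    """A mention resolved to one candidate cui, or ABSTAIN (None)."""

    mention: TermMention
    cui: str | None

    def __post_init__(self) -> None:
        if self.cui is not None and self.cui not in self.mention.candidate_cuis:
            raise ValueError(
                f"assigned cui {self.cui!r} is not a candidate of {self.mention.surface!r}"
            )


@dataclass
class AnnotatedDocument:
    doc_id: str
    year: int
    assignments: list[Assignment] = field(default_factory=list)

    def assigned_cuis(self) -> list[str]:
        """Non-ABSTAIN cuis, in mention order."""
        return [a.cui for a in self.assignments if a.cui is not None]


class ConceptGraph:
    """Undirected weighted concept graph (no self-loops)."""

    def __init__(self) -> None:
        self._adj: dict[str, dict[str, float]] = {}

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str] | tuple[str, str, float]]
    ) -> "ConceptGraph":
        g = cls()
        for edge in edges:
            if len(edge) == 3:
                u, v, w = edge  # type: ignore[misc]
            else:
                u, v = edge  # type: ignore[misc]
                w = 1.0
            g.add_edge(u, v, w)
        return g

    def add_node(self, cui: str) -> None:
        self._adj.setdefault(cui, {})

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed")
        self.add_node(u)
        self.add_node(v)
        self._adj[u][v] = self._adj[u].get(v, 0.0) + weight
        self._adj[v][u] = self._adj[v].get(u, 0.0) + weight

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._adj)

    def __contains__(self, cui: str) -> bool:
        return cui in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    def neighbors(self, cui: str) -> dict[str, float]:
        return dict(self._adj.get(cui, {}))

    def degree(self, cui: str) -> int:
        return len(self._adj.get(cui, {}))

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u in sorted(self._adj):
            for v, w in sorted(self._adj[u].items()):
                if u < v:
                    yield (u, v, w)


@dataclass(frozen=True)
class GoldSenseAnnotation:
    instance_id: str
    doc_id: str
    start: int
    end: int
    term: str
    gold_cui: str

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.doc_id, self.start, self.end)


# ---------------------------------------------------------------------------
# text normalization and term matching
# ---------------------------------------------------------------------------

_NON_ALNUM = re.compile(r"[^0-9a-z]+")


def normalize(text: str) -> str:
    """Lowercase, map punctuation to spaces, collapse whitespace.

    Deterministic and idempotent: normalize(normalize(x)) == normalize(x).
    """
    return _NON_ALNUM.sub(" ", text.lower()).strip()


def tokenize(normalized: str) -> list[tuple[str, int, int]]:
    """Tokens of a normalized string with their (start, end) offsets."""
    out = []
    pos = 0
    for tok in normalized.split():
        start = normalized.index(tok, pos)
        out.append((tok, start, start + len(tok)))
        pos = start + len(tok)
    return out


def match_terms(
    doc: Document, inventory: SenseInventory, field_name: str = "title"
) -> list[TermMention]:
    """Greedy left-to-right longest-match of inventory terms in a field.

    Matching operates over the normalized field text; resulting mention
    spans are non-overlapping and each mention carries all candidate
    concepts (monosemous and ambiguous terms alike).
    """
    text = normalize(doc.field_text(field_name))
    tokens = tokenize(text)
    max_n = inventory.max_term_tokens
    mentions: list[TermMention] = []
    i = 0
    while i < len(tokens):
        matched = False
        for n in range(min(max_n, len(tokens) - i), 0, -1):
            start = tokens[i][1]
            end = tokens[i + n - 1][2]
            phrase = text[start:end]
            candidates = inventory.lookup(phrase)
            if candidates:
                mentions.append(
                    TermMention(
                        doc_id=doc.doc_id,
                        field=field_name,
                        start=start,
                        end=end,
                        surface=phrase,
                        candidates=candidates,
                    )
                )
                i += n
                matched = True
                break
        if not matched:
            i += 1
    return mentions


# ---------------------------------------------------------------------------
# corpus I/O
# ---------------------------------------------------------------------------


def read_corpus(path: str | Path, format: str = "jsonl") -> list[Document]:
    if format == "jsonl":
        return _read_corpus_jsonl(path)
    if format == "pubmed_xml":
        return _read_corpus_pubmed(path)
    raise ValueError(f"unknown corpus format {format!r}")


def _read_corpus_jsonl(path: str | Path) -> list[Document]:
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}: line {lineno}: invalid JSON: {exc}") from exc
            docs.append(_document_from_record(record, f"{path}: line {lineno}"))
            if docs[-1].doc_id in seen:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: duplicate doc_id {docs[-1].doc_id!r}"
                )
            seen.add(docs[-1].doc_id)
    return docs


def _document_from_record(record: dict, where: str) -> Document:
    for key in ("doc_id", "title", "year"):
        if key not in record:
            raise CorpusFormatError(f"{where}: missing required field {key!r}")
    year = record["year"]
    if not isinstance(year, int):
        try:
            year = int(str(year))
        except ValueError:
            raise CorpusFormatError(
                f"{where}: field 'year': cannot parse {record['year']!r} as an integer"
            ) from None
    try:
        return Document(
            doc_id=str(record["doc_id"]),
            title=record["title"],
            year=year,
            abstract=record.get("abstract"),
        )
    except ValueError as exc:
        raise CorpusFormatError(f"{where}: {exc}") from exc


def _read_corpus_pubmed(path: str | Path) -> list[Document]:
    # Minimal MEDLINE/PubMed XML support: PMID, ArticleTitle, AbstractText,
    # and the year from PubDate (or MedlineDate prefix).
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise CorpusFormatError(f"{path}: invalid XML: {exc}") from exc
    docs: list[Document] = []
    articles = tree.getroot().iter("PubmedArticle")
    for idx, article in enumerate(articles, start=1):
        where = f"{path}: article {idx}"
        pmid = article.findtext(".//PMID")
        title = article.findtext(".//ArticleTitle")
        abstract_parts = [el.text or "" for el in article.findall(".//AbstractText")]
        year_text = article.findtext(".//PubDate/Year")
        if year_text is None:
            medline_date = article.findtext(".//PubDate/MedlineDate") or ""
            match = re.match(r"(\d{4})", medline_date)
            year_text = match.group(1) if match else None
        if pmid is None:
            raise CorpusFormatError(f"{where}: missing PMID")
        if title is None:
            raise CorpusFormatError(f"{where}: missing ArticleTitle")
        if year_text is None:
            raise CorpusFormatError(f"{where}: missing publication year")
        try:
            year = int(year_text)
        except ValueError:
            raise CorpusFormatError(
                f"{where}: cannot parse year {year_text!r} as an integer"
            ) from None
        docs.append(
            Document(
                doc_id=pmid,
                title=title,
                year=year,
                abstract=" ".join(abstract_parts) if abstract_parts else None,
            )
        )
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            record: dict = {"doc_id": doc.doc_id, "title": doc.title, "year": doc.year}
            if doc.abstract is not None:
                record["abstract"] = doc.abstract
            fh.write(json.dumps(record, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, n_cols: tuple[int, ...], what: str) -> Iterator[list[str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) not in n_cols:
                expected = " or ".join(str(n) for n in n_cols)
                raise CorpusFormatError(
                    f"{path}: line {lineno}: {what} rows must have {expected} "
                    f"tab-separated columns, found {len(fields)}"
                )
            yield fields


def read_inventory(
    path: str | Path, type_map: Mapping[str, set[str]] | None = None
) -> SenseInventory:
    """Read a term/cui/description TSV into a SenseInventory.

    If *type_map* is given, concepts are decorated with their semantic types.
    """
    inv = SenseInventory()
    for term, cui, description in _read_tsv(path, (3,), "inventory"):
        types = frozenset(type_map.get(cui, set())) if type_map else frozenset()
        inv.add(term, Concept(cui=cui, description=description, semantic_types=types))
    return inv


def write_inventory(inventory: SenseInventory, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, concepts in inventory.items():
            for c in concepts:
                fh.write(f"{term}\t{c.cui}\t{c.description}\n")


def read_semantic_types(path: str | Path) -> dict[str, set[str]]:
    type_map: dict[str, set[str]] = {}
    for cui, sem_type in _read_tsv(path, (2,), "semantic type"):
        type_map.setdefault(cui, set()).add(sem_type)
    return type_map


def write_semantic_types(type_map: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cui in sorted(type_map):
            for sem_type in sorted(type_map[cui]):
                fh.write(f"{cui}\t{sem_type}\n")


def read_relations(path: str | Path) -> ConceptGraph:
    graph = ConceptGraph()
    for fields in _read_tsv(path, (2, 3), "relation"):
        weight = float(fields[2]) if len(fields) == 3 else 1.0
        graph.add_edge(fields[0], fields[1], weight)
    return graph


def write_relations(graph: ConceptGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, w in graph.edges():
            fh.write(f"{u}\t{v}\t{w:g}\n")


def read_gold(path: str | Path) -> list[GoldSenseAnnotation]:
    out = []
    for inst, doc_id, start, end, term, cui in _read_tsv(path, (6,), "gold sense"):
        try:
            span = (int(start), int(end))
        except ValueError:
            raise CorpusFormatError(
                f"{path}: gold instance {inst!r}: non-integer span ({start!r}, {end!r})"
            ) from None
        out.append(
            GoldSenseAnnotation(
                instance_id=inst, doc_id=doc_id, start=span[0], end=span[1],
                term=term, gold_cui=cui,
            )
        )
    return out


def write_gold(gold: Iterable[GoldSenseAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in gold:
            fh.write(
                f"{g.instance_id}\t{g.doc_id}\t{g.start}\t{g.end}\t{g.term}\t{g.gold_cui}\n"
            )


# ---------------------------------------------------------------------------
# annotation I/O (JSON Lines, one object per document)
# ---------------------------------------------------------------------------


def write_annotations(annotated: Iterable[AnnotatedDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in annotated:
            record = {
                "doc_id": doc.doc_id,
                "year": doc.year,
                "assignments": [
                    {
                        "start": a.mention.start,
                        "end": a.mention.end,
                        "surface": a.mention.surface,
                        "candidates": list(a.mention.candidate_cuis),
                        "chosen": a.cui,
                    }
                    for a in doc.assignments
                ],
            }
            fh.write(json.dumps(record, sort_keys=True) + "\n")


def read_annotations(path: str | Path) -> list[AnnotatedDocument]:
    """Read annotations back; candidate concepts are reconstructed as bare cuis."""
    out: list[AnnotatedDocument] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}: line {lineno}: invalid JSON: {exc}") from exc
            assignments = []
            for a in record["assignments"]:
                mention = TermMention(
                    doc_id=record["doc_id"],
                    field="title",
                    start=a["start"],
                    end=a["end"],
                    surface=a["surface"],
                    candidates=tuple(Concept(cui=c) for c in a["candidates"]),
                )
                assignments.append(Assignment(mention=mention, cui=a["chosen"]))
            out.append(
                AnnotatedDocument(
                    doc_id=record["doc_id"], year=record["year"], assignments=assignments
                )
            )
    return out
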