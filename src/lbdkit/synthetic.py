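"""Synthetic toy worlds: sense inventory, semantic types, relation graph,
dated corpus with gold sense annotations, planted A-B-C discovery triples,
and ambiguity confounds.

The generator emits exactly the file formats the rest of the package
consumes, so every pipeline stage is testable without external data. All
randomness flows from a single seed through one named generator.

Structural guarantees (by construction, not by chance):

* each planted triple (a, b, c) has at least one pre-cutoff title realizing
  (a, b), at least one realizing (b, c), and no pre-cutoff title in which a
  and c co-occur; realized triples have a post-cutoff (a, c) title;
* confound structures pair an ambiguous term's sense b1 with a fresh
  concept A and its sense b2 with a fresh concept C, with no true A–C link
  anywhere, so a sense-collapsing annotator manufactures the spurious
  (A, C) pair while a gold annotator does not;
* every mention in every generated title has a gold sense annotation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import (
    Concept,
    ConceptGraph,
    Document,
    GoldSenseAnnotation,
    SenseInventory,
    write_corpus,
    write_gold,
    write_inventory,
    write_relations,
    write_semantic_types,
)

__all__ = [
    "WorldConfig",
    "PlantedTriple",
    "World",
    "generate_world",
    "plant_ambiguity_confound",
    "build_world",
    "write_world",
]


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of a synthetic world. Defaults run the full pipeline in seconds."""

    n_concepts: int = 200
    n_terms: int = 150
    ambiguity_rate: float = 0.3
    max_senses: int = 3
    multiword_fraction: float = 0.2
    n_semantic_types: int = 10
    excluded_type_fraction: float = 0.2
    n_docs_pre: int = 800
    n_docs_post: int = 400
    cutoff_year: int = 2005
    year_span: int = 5
    n_planted_triples: int = 30
    n_confounds: int = 5
    distractor_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_concepts", "n_terms", "max_senses", "n_semantic_types",
            "n_docs_pre", "n_docs_post", "year_span",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"WorldConfig.{name} must be positive")
        for name in (
            "ambiguity_rate", "multiword_fraction", "excluded_type_fraction",
            "distractor_rate",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"WorldConfig.{name} must be in [0, 1]")
        if self.max_senses < 2:
            raise ValueError("WorldConfig.max_senses must be >= 2")
        if self.n_planted_triples < 0 or self.n_confounds < 0:
            raise ValueError("triple/confound counts must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class PlantedTriple:
    """An A-B-C discovery planted in the corpus."""

    cui_a: str
    cui_b: str
    cui_c: str
    realized: bool = True

    @property
    def hidden_pair(self) -> tuple[str, str]:
        a, c = sorted((self.cui_a, self.cui_c))
        return (a, c)


@dataclass
class World:
    config: WorldConfig
    concepts: dict[str, Concept]
    inventory: SenseInventory
    type_map: dict[str, set[str]]
    semantic_types: list[str]
    excluded_semantic_types: set[str]
    graph: ConceptGraph
    documents: list[Document]
    gold: list[GoldSenseAnnotation]
    triples: list[PlantedTriple]
    spurious_pairs: list[tuple[str, str]] = field(default_factory=list)
    reserved_concepts: list[str] = field(default_factory=list)
    n_confounds_planted: int = 0

    def pre_documents(self) -> list[Document]:
        return [d for d in self.documents if d.year <= self.config.cutoff_year]

    def post_documents(self) -> list[Document]:
        return [d for d in self.documents if d.year > self.config.cutoff_year]


class _Builder:
    """Mutable state shared by world generation and confound planting."""

    def __init__(self, world: World, rng: np.random.Generator) -> None:
        self.world = world
        self.rng = rng
        self.terms_for_concept: dict[str, list[str]] = {}
        for term, cands in world.inventory.items():
            for c in cands:
                self.terms_for_concept.setdefault(c.cui, []).append(term)

    def realize(self, cui: str) -> str:
        """A surface term realizing *cui* (random choice among coverers)."""
        terms = self.terms_for_concept[cui]
        return terms[self.rng.integers(len(terms))] if len(terms) > 1 else terms[0]

    def emit_doc(
        self,
        doc_id: str,
        cuis: list[str],
        year: int,
        forced_terms: dict[str, str] | None = None,
    ) -> None:
        order = self.rng.permutation(len(cuis))
        surfaces = []
        for k in order:
            cui = cuis[k]
            term = (forced_terms or {}).get(cui) or self.realize(cui)
            surfaces.append((term, cui))
        title_parts = []
        golds = []
        pos = 0
        for surface, cui in surfaces:
            start = pos
            end = start + len(surface)
            title_parts.append(surface)
            golds.append((start, end, surface, cui))
            pos = end + 1
        title = " ".join(title_parts)
        self.world.documents.append(Document(doc_id=doc_id, title=title, year=year))
        for k, (start, end, surface, cui) in enumerate(golds):
            self.world.gold.append(
                GoldSenseAnnotation(
                    instance_id=f"{doc_id}.{k}",
                    doc_id=doc_id,
                    start=start,
                    end=end,
                    term=surface,
                    gold_cui=cui,
                )
            )
        for i in range(len(cuis)):
            for j in range(i + 1, len(cuis)):
                if cuis[i] != cuis[j]:
                    self.world.graph.add_edge(cuis[i], cuis[j], 1.0)


def generate_world(config: WorldConfig) -> World:
    """Generate a complete world; deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)

    n_triple_concepts = 3 * config.n_planted_triples
    n_reserved = 2 * config.n_confounds
    n_pool = config.n_concepts - n_triple_concepts - n_reserved
    needs_pool = config.distractor_rate > 0 or config.n_planted_triples == 0
    if n_pool < 0 or (needs_pool and n_pool < 2):
        raise ValueError(
            f"infeasible config: n_concepts={config.n_concepts} leaves only "
            f"{n_pool} concepts after {config.n_planted_triples} planted triples "
            f"({n_triple_concepts} concepts) and {config.n_confounds} confound "
            f"reservations ({n_reserved} concepts); distractor titles need at "
            f"least 2 spare concepts"
        )
    if config.n_docs_pre < 2 * config.n_planted_triples:
        raise ValueError(
            f"infeasible config: n_docs_pre={config.n_docs_pre} cannot hold the "
            f"{2 * config.n_planted_triples} documents required by "
            f"{config.n_planted_triples} planted triples"
        )
    if config.n_docs_post < config.n_planted_triples:
        raise ValueError(
            f"infeasible config: n_docs_post={config.n_docs_post} cannot realize "
            f"{config.n_planted_triples} planted (A,C) documents"
        )

    cuis = [f"C{i:07d}" for i in range(config.n_concepts)]
    shuffled = [cuis[i] for i in rng.permutation(config.n_concepts)]
    triple_cuis = shuffled[:n_triple_concepts]
    reserved = shuffled[n_triple_concepts:n_triple_concepts + n_reserved]
    pool = shuffled[n_triple_concepts + n_reserved:]

    # semantic types: the last chunk of the declared set is the exclusion list
    semantic_types = [f"T{i:03d}" for i in range(config.n_semantic_types)]
    n_excluded = int(round(config.excluded_type_fraction * config.n_semantic_types))
    n_excluded = min(n_excluded, config.n_semantic_types - 1)
    excluded = set(semantic_types[config.n_semantic_types - n_excluded:]) if n_excluded else set()
    informative = [t for t in semantic_types if t not in excluded]

    type_map: dict[str, set[str]] = {}
    for cui in triple_cuis + reserved:
        type_map[cui] = {informative[rng.integers(len(informative))]}
    for cui in pool:
        if excluded and rng.random() < config.excluded_type_fraction:
            type_map[cui] = {sorted(excluded)[rng.integers(len(excluded))]}
        else:
            type_map[cui] = {informative[rng.integers(len(informative))]}

    concepts = {
        cui: Concept(
            cui=cui,
            description=f"synthetic concept {cui}",
            semantic_types=frozenset(type_map[cui]),
        )
        for cui in cuis
    }

    # term → sense assignment: reserved concepts get their terms only when
    # confounds are planted, everything else must be covered by >= 1 term
    assignable = [c for c in shuffled if c not in set(reserved)]
    n_ambiguous = int(round(config.ambiguity_rate * config.n_terms))
    capacities = [1] * (config.n_terms - n_ambiguous) + [
        int(rng.integers(2, config.max_senses + 1)) for _ in range(n_ambiguous)
    ]
    slots = [t for t, cap in enumerate(capacities) for _ in range(cap)]
    if len(slots) < len(assignable):
        raise ValueError(
            f"infeasible config: {config.n_terms} terms provide {len(slots)} sense "
            f"slots but {len(assignable)} concepts need coverage; increase n_terms, "
            f"ambiguity_rate or max_senses"
        )
    slots = [slots[i] for i in rng.permutation(len(slots))]
    term_senses: list[list[str]] = [[] for _ in range(config.n_terms)]
    for concept_cui, term_idx in zip(assignable, slots):
        term_senses[term_idx].append(concept_cui)
    used = list(assignable)
    for term_idx in (slots[i] for i in range(len(assignable), len(slots))):
        for _ in range(50):
            candidate = used[rng.integers(len(used))]
            if candidate not in term_senses[term_idx]:
                term_senses[term_idx].append(candidate)
                break
        # on repeated collision the slot is silently dropped (term gets
        # fewer senses); harmless for every planted guarantee

    inventory = SenseInventory()
    for term_idx, senses in enumerate(term_senses):
        if not senses:
            continue
        surface = f"term{term_idx:04d}"
        if rng.random() < config.multiword_fraction:
            surface = f"{surface} extra"
        for cui in senses:
            inventory.add(surface, concepts[cui])

    world = World(
        config=config,
        concepts=concepts,
        inventory=inventory,
        type_map=type_map,
        semantic_types=semantic_types,
        excluded_semantic_types=excluded,
        graph=ConceptGraph(),
        documents=[],
        gold=[],
        triples=[],
        reserved_concepts=list(reserved),
    )
    builder = _Builder(world, rng)

    triples = [
        PlantedTriple(
            cui_a=triple_cuis[3 * k],
            cui_b=triple_cuis[3 * k + 1],
            cui_c=triple_cuis[3 * k + 2],
            realized=True,
        )
        for k in range(config.n_planted_triples)
    ]
    world.triples = triples

    pre_years = list(range(config.cutoff_year - config.year_span + 1, config.cutoff_year + 1))
    post_years = list(range(config.cutoff_year + 1, config.cutoff_year + config.year_span + 1))

    def pre_year() -> int:
        return pre_years[rng.integers(len(pre_years))]

    def post_year() -> int:
        return post_years[rng.integers(len(post_years))]

    def distractor_pair() -> list[str]:
        i, j = rng.choice(len(pool), size=2, replace=False)
        return [pool[i], pool[j]]

    doc_counter = 0

    def next_id() -> str:
        nonlocal doc_counter
        doc_counter += 1
        return f"doc{doc_counter:05d}"

    # guaranteed pre-cutoff realizations of (a, b) and (b, c)
    for t in triples:
        builder.emit_doc(next_id(), [t.cui_a, t.cui_b], pre_year())
        builder.emit_doc(next_id(), [t.cui_b, t.cui_c], pre_year())
    for _ in range(config.n_docs_pre - 2 * config.n_planted_triples):
        if not triples or rng.random() < config.distractor_rate:
            cuis = distractor_pair()
        else:
            t = triples[rng.integers(len(triples))]
            cuis = [t.cui_a, t.cui_b] if rng.random() < 0.5 else [t.cui_b, t.cui_c]
        builder.emit_doc(next_id(), cuis, pre_year())

    # post-cutoff: realize every planted (a, c) once, then fill
    for t in triples:
        builder.emit_doc(next_id(), [t.cui_a, t.cui_c], post_year())
    for _ in range(config.n_docs_post - config.n_planted_triples):
        if not triples or rng.random() < config.distractor_rate:
            cuis = distractor_pair()
        else:
            t = triples[rng.integers(len(triples))]
            cuis = [t.cui_a, t.cui_c]
        builder.emit_doc(next_id(), cuis, post_year())

    return world


def plant_ambiguity_confound(world: World, n_confounds: int, seed: int) -> World:
    """Add confound structures to a generated world.

    Each confound reuses an existing ambiguous term: its first sense b1
    co-occurs (pre-cutoff) with a fresh concept A and its second sense b2
    with a fresh concept C, with no true A–C connection planted anywhere.
    The spurious (A, C) pairs that a sense-collapsing annotator would
    manufacture are recorded in ``world.spurious_pairs``.
    """
    if n_confounds == 0:
        return world

    def filter_safe(term: str) -> bool:
        # every sense must survive the semantic-type filter, or the
        # collapsed middle concept could be dropped before matrix building
        return all(
            not world.type_map.get(c.cui, set())
            or not world.type_map[c.cui] <= world.excluded_semantic_types
            for c in world.inventory.lookup(term)
        )

    ambiguous = sorted(t for t in world.inventory.ambiguous_terms() if filter_safe(t))
    if len(ambiguous) < n_confounds:
        raise ValueError(
            f"insufficient ambiguous terms: need {n_confounds}, "
            f"inventory has {len(ambiguous)} with filter-surviving senses"
        )
    if len(world.reserved_concepts) < 2 * n_confounds:
        raise ValueError(
            f"insufficient reserved concepts: need {2 * n_confounds}, "
            f"world reserved {len(world.reserved_concepts)} "
            f"(set WorldConfig.n_confounds when generating)"
        )
    rng = np.random.default_rng(seed)
    world = dataclasses.replace(
        world,
        documents=list(world.documents),
        gold=list(world.gold),
        spurious_pairs=list(world.spurious_pairs),
        reserved_concepts=list(world.reserved_concepts),
    )
    chosen_terms = [ambiguous[i] for i in rng.choice(len(ambiguous), n_confounds, replace=False)]
    builder = _Builder(world, rng)
    doc_counter = len(world.documents)
    pre_years = list(
        range(world.config.cutoff_year - world.config.year_span + 1, world.config.cutoff_year + 1)
    )
    for k, term in enumerate(chosen_terms):
        senses = world.inventory.lookup(term)
        b1, b2 = senses[0].cui, senses[1].cui
        cui_a = world.reserved_concepts.pop()
        cui_c = world.reserved_concepts.pop()
        # fresh monosemous terms so A and C survive any annotator unchanged
        for cui, tag in ((cui_a, "a"), (cui_c, "c")):
            surface = f"cterm{k:04d}{tag}"
            world.inventory.add(surface, world.concepts[cui])
            builder.terms_for_concept.setdefault(cui, []).append(surface)
        # the middle senses are realized through the ambiguous term itself,
        # so a sense-collapsing annotator maps both documents to one middle
        for pair, mid in (([cui_a, b1], b1), ([b2, cui_c], b2)):
            doc_counter += 1
            builder.emit_doc(
                f"doc{doc_counter:05d}",
                pair,
                pre_years[rng.integers(len(pre_years))],
                forced_terms={mid: term},
            )
        world.spurious_pairs.append(tuple(sorted((cui_a, cui_c))))
    world.n_confounds_planted += n_confounds
    return world


def build_world(config: WorldConfig) -> World:
    """generate_world plus confound planting per config.n_confounds."""
    world = generate_world(config)
    if config.n_confounds:
        world = plant_ambiguity_confound(world, config.n_confounds, config.seed + 1)
    return world


def write_world(world: World, outdir: str | Path) -> dict:
    """Write the five input files plus a manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_corpus(world.documents, outdir / "corpus.jsonl")
    write_inventory(world.inventory, outdir / "inventory.tsv")
    write_semantic_types(world.type_map, outdir / "semantic_types.tsv")
    write_relations(world.graph, outdir / "relations.tsv")
    write_gold(world.gold, outdir / "gold.tsv")
    manifest = {
        "config": world.config.to_dict(),
        "seed": world.config.seed,
        "n_documents": len(world.documents),
        "n_gold_instances": len(world.gold),
        "semantic_types": world.semantic_types,
        "excluded_semantic_types": sorted(world.excluded_semantic_types),
        "planted_triples": [
            {"a": t.cui_a, "b": t.cui_b, "c": t.cui_c, "realized": t.realized}
            for t in world.triples
        ],
        "spurious_pairs": [list(p) for p in world.spurious_pairs],
        "n_confounds": world.n_confounds_planted,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
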