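import math

import numpy as np
import pytest

from lbdkit.corpus import (
    Concept,
    ConceptGraph,
    Document,
    GoldSenseAnnotation,
    SenseInventory,
    TermMention,
)
from lbdkit.evaluation import evaluate_wsd
from lbdkit.wsd import (
    CollapseBackend,
    FeatureVector,
    OracleBackend,
    PPRBackend,
    PersonalizationVector,
    RandomBackend,
    VSMBackend,
    annotate_corpus,
    cosine_similarity,
    extract_features,
    generate_pseudo_labels,
    personalized_pagerank,
    train_centroids,
)


def _mention(doc_id, cuis, start=0, end=4, surface="term"):
    return TermMention(
        doc_id=doc_id,
        field="title",
        start=start,
        end=end,
        surface=surface,
        candidates=tuple(Concept(cui=c) for c in cuis),
    )


def _doc(doc_id="d1", title="some title", year=2000):
    return Document(doc_id=doc_id, title=title, year=year)


def dense_ppr(graph: ConceptGraph, personalization: dict, damping: float) -> dict:
    """Independent oracle: solve (I - d·M) r = (1-d)·p directly."""
    nodes = sorted(graph.nodes)
    index = {c: i for i, c in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for u, v, w in graph.edges():
        W[index[u], index[v]] = w
        W[index[v], index[u]] = w
    p = np.zeros(n)
    for c, w in personalization.items():
        p[index[c]] = w
    p /= p.sum()
    M = np.zeros((n, n))
    for j in range(n):
        col = W[:, j]
        M[:, j] = p if col.sum() == 0 else col / col.sum()
    r = np.linalg.solve(np.eye(n) - damping * M, (1 - damping) * p)
    r /= r.sum()
    return {c: r[index[c]] for c in nodes}


class TestPersonalizedPagerank:
    def test_two_node_closed_form(self):
        # r(a) = d·r(b) + (1-d), r(b) = d·r(a)  =>  r(a) = (1-d)/(1-d²)
        g = ConceptGraph.from_edges([("a", "b")])
        r = personalized_pagerank(g, {"a": 1.0}, damping=0.85)
        expected_a = 0.15 / (1 - 0.85**2)
        assert r["a"] == pytest.approx(expected_a, abs=1e-8)
        assert r["b"] == pytest.approx(1 - expected_a, abs=1e-8)

    def test_triangle_uniform_personalization_is_uniform(self):
        g = ConceptGraph.from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        r = personalized_pagerank(g, PersonalizationVector.uniform(["a", "b", "c"]))
        for c in "abc":
            assert r[c] == pytest.approx(1 / 3, abs=1e-9)

    def test_damping_zero_returns_personalization(self):
        g = ConceptGraph.from_edges([("a", "b"), ("b", "c")])
        r = personalized_pagerank(g, {"a": 0.7, "c": 0.3}, damping=0.0)
        assert r["a"] == pytest.approx(0.7, abs=1e-9)
        assert r["c"] == pytest.approx(0.3, abs=1e-9)
        assert r["b"] == pytest.approx(0.0, abs=1e-9)

    def test_scores_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 10))
            g = ConceptGraph()
            for i in range(n):
                g.add_node(f"n{i}")
            for _ in range(int(rng.integers(1, 2 * n))):
                u, v = rng.choice(n, size=2, replace=False)
                g.add_edge(f"n{u}", f"n{v}")
            r = personalized_pagerank(g, {"n0": 1.0})
            assert abs(sum(r.scores.values()) - 1.0) < 1e-8

    def test_agrees_with_dense_linear_solve(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(2, 11))
            g = ConceptGraph()
            for i in range(n):
                g.add_node(f"n{i}")
            for _ in range(int(rng.integers(1, 3 * n))):
                u, v = rng.choice(n, size=2, replace=False)
                g.add_edge(f"n{u}", f"n{v}")
            k = int(rng.integers(1, n + 1))
            targets = rng.choice(n, size=k, replace=False)
            p = {f"n{t}": 1.0 / k for t in targets}
            mine = personalized_pagerank(g, p)
            oracle = dense_ppr(g, p, 0.85)
            for c in oracle:
                assert mine[c] == pytest.approx(oracle[c], abs=1e-6)

    def test_dangling_mass_goes_to_personalization(self):
        g = ConceptGraph()
        g.add_node("isolated")
        g.add_edge("a", "b")
        r = personalized_pagerank(g, {"isolated": 1.0})
        # teleport + dangling redistribution keep all mass on the isolated node
        assert r["isolated"] == pytest.approx(1.0, abs=1e-8)

    def test_errors(self):
        g = ConceptGraph.from_edges([("a", "b")])
        with pytest.raises(ValueError, match="empty"):
            personalized_pagerank(ConceptGraph(), {"a": 1.0})
        with pytest.raises(ValueError, match="empty"):
            personalized_pagerank(g, {})
        with pytest.raises(ValueError, match="not in graph"):
            personalized_pagerank(g, {"zz": 1.0})
        with pytest.raises(ValueError, match="damping"):
            personalized_pagerank(g, {"a": 1.0}, damping=1.0)


class TestRandomBackend:
    def test_monosemous_always_that_candidate(self):
        doc = _doc()
        for seed in range(5):
            ann = RandomBackend(seed).annotate(doc, [_mention("d1", ["C1"])])
            assert ann.assignments[0].cui == "C1"

    def test_deterministic_given_seed(self, default_world):
        docs = default_world.documents[:50]
        inv = default_world.inventory
        a1 = annotate_corpus(docs, inv, RandomBackend(seed=9))
        a2 = annotate_corpus(docs, inv, RandomBackend(seed=9))
        assert a1 == a2

    def test_binomial_agreement_rate(self):
        # 10,000 2-way mentions: gold-agreement within 3 binomial SDs of 0.5
        n = 10_000
        doc = _doc()
        mentions = [_mention("d1", ["Ca", "Cb"], start=i, end=i + 1) for i in range(n)]
        ann = RandomBackend(seed=0).annotate(doc, mentions)
        hits = sum(a.cui == "Ca" for a in ann.assignments)
        sd = math.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * sd


class TestOracleBackend:
    def _setup(self, n, cuis=("Ca", "Cb")):
        doc = _doc()
        mentions = [_mention("d1", list(cuis), start=i, end=i + 1) for i in range(n)]
        gold = [
            GoldSenseAnnotation(
                instance_id=f"i{i}", doc_id="d1", start=i, end=i + 1,
                term="term", gold_cui=cuis[0],
            )
            for i in range(n)
        ]
        return doc, mentions, gold

    def test_accuracy_one_matches_gold(self):
        doc, mentions, gold = self._setup(200)
        ann = OracleBackend(gold, 1.0, seed=0).annotate(doc, mentions)
        assert all(a.cui == "Ca" for a in ann.assignments)

    def test_accuracy_zero_two_way_never_gold(self):
        doc, mentions, gold = self._setup(200)
        ann = OracleBackend(gold, 0.0, seed=0).annotate(doc, mentions)
        assert all(a.cui == "Cb" for a in ann.assignments)

    @pytest.mark.parametrize("target", [0.2, 0.5, 0.7, 0.8])
    def test_measured_accuracy_within_three_binomial_sd(self, target):
        n = 10_000
        doc, mentions, gold = self._setup(n)
        ann = OracleBackend(gold, target, seed=1).annotate(doc, mentions)
        hits = sum(a.cui == "Ca" for a in ann.assignments)
        sd = math.sqrt(target * (1 - target) / n)
        assert abs(hits / n - target) < 3 * sd

    def test_missing_gold_for_ambiguous_mention_errors(self):
        doc = _doc()
        backend = OracleBackend([], 0.5, seed=0)
        with pytest.raises(ValueError, match="no gold annotation"):
            backend.annotate(doc, [_mention("d1", ["Ca", "Cb"])])

    def test_monosemous_always_correct_even_at_zero_accuracy(self):
        doc = _doc()
        ann = OracleBackend([], 0.0, seed=0).annotate(doc, [_mention("d1", ["C1"])])
        assert ann.assignments[0].cui == "C1"


class TestPPRBackend:
    def test_context_edge_decides_sense(self):
        # one ambiguous mention {s1, s2}, one monosemous context m, edge m—s1:
        # brute-force PPR on the 3-node graph ranks s1 above s2
        g = ConceptGraph.from_edges([("m", "s1")])
        g.add_node("s2")
        doc = _doc(title="amb ctx")
        mentions = [
            _mention("d1", ["s1", "s2"], start=0, end=3, surface="amb"),
            _mention("d1", ["m"], start=4, end=7, surface="ctx"),
        ]
        oracle = dense_ppr(g, {"s1": 1 / 3, "s2": 1 / 3, "m": 1 / 3}, 0.85)
        assert oracle["s1"] > oracle["s2"]
        ann = PPRBackend(g).annotate(doc, mentions)
        assert ann.assignments[0].cui == "s1"
        assert ann.assignments[1].cui == "m"

    def test_isolated_tied_candidates_lexicographic(self):
        g = ConceptGraph.from_edges([("m", "x")])
        g.add_node("s2")
        g.add_node("s1")
        doc = _doc(title="amb ctx")
        mentions = [
            _mention("d1", ["s2", "s1"], start=0, end=3, surface="amb"),
            _mention("d1", ["m"], start=4, end=7, surface="ctx"),
        ]
        ann = PPRBackend(g).annotate(doc, mentions)
        assert ann.assignments[0].cui == "s1"

    def test_lone_ambiguous_mention_without_edges_abstains(self):
        g = ConceptGraph()
        g.add_node("s1")
        g.add_node("s2")
        doc = _doc(title="amb")
        ann = PPRBackend(g).annotate(doc, [_mention("d1", ["s1", "s2"], 0, 3, "amb")])
        assert ann.assignments[0].cui is None

    def test_all_candidates_absent_from_graph_abstains(self):
        g = ConceptGraph.from_edges([("m", "x")])
        doc = _doc(title="amb ctx")
        mentions = [
            _mention("d1", ["zz1", "zz2"], start=0, end=3, surface="amb"),
            _mention("d1", ["m"], start=4, end=7, surface="ctx"),
        ]
        ann = PPRBackend(g).annotate(doc, mentions)
        assert ann.assignments[0].cui is None

    def test_per_target_mode_excludes_own_candidates(self):
        g = ConceptGraph.from_edges([("m", "s1")])
        g.add_node("s2")
        doc = _doc(title="amb ctx")
        mentions = [
            _mention("d1", ["s1", "s2"], start=0, end=3, surface="amb"),
            _mention("d1", ["m"], start=4, end=7, surface="ctx"),
        ]
        ann = PPRBackend(g, mode="per_target").annotate(doc, mentions)
        assert ann.assignments[0].cui == "s1"

    def test_beats_random_on_informative_graphs(self):
        # averaged over >= 5 seeded worlds whose graphs link gold senses to
        # their context concepts
        from lbdkit.synthetic import WorldConfig, generate_world

        ppr_acc, rnd_acc = [], []
        for seed in range(5):
            w = generate_world(
                WorldConfig(
                    n_concepts=60, n_terms=50, n_planted_triples=8, n_confounds=0,
                    n_docs_pre=150, n_docs_post=80, seed=seed,
                )
            )
            ppr = annotate_corpus(w.documents, w.inventory, PPRBackend(w.graph))
            rnd = annotate_corpus(w.documents, w.inventory, RandomBackend(seed=seed))
            ppr_acc.append(evaluate_wsd(ppr, w.gold).precision)
            rnd_acc.append(evaluate_wsd(rnd, w.gold).precision)
        assert np.mean(ppr_acc) > np.mean(rnd_acc)


class TestCollapseBackend:
    def test_always_smallest_candidate(self):
        doc = _doc()
        ann = CollapseBackend().annotate(doc, [_mention("d1", ["Cb", "Ca"])])
        assert ann.assignments[0].cui == "Ca"


class TestExtractFeatures:
    def test_hand_trace_sentence_plus_window(self):
        # sentence content words {fever} plus window tokens {causes, fever}
        doc = _doc(title="cold causes fever")
        mention = _mention("d1", ["C1"], start=0, end=4, surface="cold")
        fv = extract_features(doc, mention, window=4, stopwords=frozenset({"causes"}))
        assert fv.features == {"fever": 2.0, "causes": 1.0}

    def test_mention_spanning_whole_title_is_empty(self):
        doc = _doc(title="common cold")
        mention = _mention("d1", ["C1"], start=0, end=11, surface="common cold")
        fv = extract_features(doc, mention, window=4)
        assert fv.features == {}

    def test_window_zero_gives_sentence_content_words_only(self):
        doc = _doc(title="cold causes fever")
        mention = _mention("d1", ["C1"], start=0, end=4, surface="cold")
        fv = extract_features(doc, mention, window=0, stopwords=frozenset({"causes"}))
        assert fv.features == {"fever": 1.0}

    def test_sentence_boundary_limits_sentence_features(self):
        doc = _doc(title="cold in winter. fever treatment here")
        mention = _mention("d1", ["C1"], start=0, end=4, surface="cold")
        fv = extract_features(doc, mention, window=1, stopwords=frozenset({"in"}))
        # sentence 1 content: winter; window ±1: in
        assert fv.features == {"winter": 1.0, "in": 1.0}


class TestCentroidsAndVSM:
    def test_single_instance_centroid_is_the_instance(self):
        fv = FeatureVector(features={"a": 1.0, "b": 2.0})
        cents = train_centroids([(fv, "C1")])
        assert cents["C1"].vector == {"a": 1.0, "b": 2.0}
        assert cents["C1"].support == 1

    def test_mean_of_two_instances(self):
        cents = train_centroids(
            [(FeatureVector({"a": 1.0}), "C1"), (FeatureVector({"a": 3.0}), "C1")]
        )
        assert cents["C1"].vector == {"a": 2.0}

    def test_centroid_equals_numpy_mean_oracle(self):
        rng = np.random.default_rng(5)
        feats = [f"f{i}" for i in range(6)]
        instances = []
        for _ in range(40):
            vec = {f: float(rng.integers(0, 4)) for f in feats}
            instances.append((FeatureVector(vec), f"C{rng.integers(3)}"))
        cents = train_centroids(instances)
        for cui, cent in cents.items():
            mine = np.array([cent.vector.get(f, 0.0) for f in feats])
            arrays = np.array(
                [[fv.features[f] for f in feats] for fv, c in instances if c == cui]
            )
            assert np.allclose(mine, arrays.mean(axis=0))

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            train_centroids([])

    def test_cosine_argmax(self):
        # instance (2,1): cos with (1,0) = 0.894 > cos with (0,1) = 0.447
        assert cosine_similarity({"f1": 2, "f2": 1}, {"f1": 1}) == pytest.approx(0.894, abs=1e-3)
        assert cosine_similarity({"f1": 2, "f2": 1}, {"f2": 1}) == pytest.approx(0.447, abs=1e-3)
        cents = train_centroids(
            [(FeatureVector({"f1": 1.0}), "s1"), (FeatureVector({"f2": 1.0}), "s2")]
        )
        doc = _doc(title="amb f1 f1 f2")
        mention = _mention("d1", ["s1", "s2"], start=0, end=3, surface="amb")
        ann = VSMBackend(cents, window=4, stopwords=frozenset()).annotate(doc, [mention])
        assert ann.assignments[0].cui == "s1"

    def test_zero_feature_vector_abstains(self):
        cents = train_centroids([(FeatureVector({"f1": 1.0}), "s1"),
                                 (FeatureVector({"f2": 1.0}), "s2")])
        doc = _doc(title="amb")
        mention = _mention("d1", ["s1", "s2"], start=0, end=3, surface="amb")
        ann = VSMBackend(cents).annotate(doc, [mention])
        assert ann.assignments[0].cui is None

    def test_identical_centroids_tie_break_lexicographic(self):
        cents = train_centroids([(FeatureVector({"f1": 1.0}), "s2"),
                                 (FeatureVector({"f1": 1.0}), "s1")])
        doc = _doc(title="amb f1")
        mention = _mention("d1", ["s2", "s1"], start=0, end=3, surface="amb")
        ann = VSMBackend(cents, stopwords=frozenset()).annotate(doc, [mention])
        assert ann.assignments[0].cui == "s1"

    def test_no_candidate_centroid_abstains(self):
        doc = _doc(title="amb f1")
        mention = _mention("d1", ["s1", "s2"], start=0, end=3, surface="amb")
        ann = VSMBackend({}, stopwords=frozenset()).annotate(doc, [mention])
        assert ann.assignments[0].cui is None


class TestPseudoLabels:
    def test_monosemous_relative_yields_labeled_instances(self):
        s1 = Concept(cui="C1", description="common cold")
        s2 = Concept(cui="C2", description="cold temperature")
        fever = Concept(cui="C9", description="fever")
        inv = SenseInventory()
        inv.add("cold", s1)
        inv.add("cold", s2)
        inv.add("common cold", s1)  # monosemous synonym of sense s1
        inv.add("fever", fever)
        docs = [_doc("d1", "common cold with fever", 2000)]
        labeled = generate_pseudo_labels(docs, inv, stopwords=frozenset({"with"}))
        assert [cui for _, cui in labeled] == ["C1"]
        assert labeled[0][0].features == {"fever": 2.0, "with": 1.0}

    def test_no_monosemous_terms_gives_empty_set(self):
        inv = SenseInventory()
        inv.add("cold", Concept(cui="C1"))
        inv.add("cold", Concept(cui="C2"))
        docs = [_doc("d1", "cold cold", 2000)]
        assert generate_pseudo_labels(docs, inv) == []

    def test_count_matches_generator_truth(self, small_world):
        # every mention of a monosemous term whose concept doubles as an
        # ambiguous sense yields exactly one instance
        inv = small_world.inventory
        ambiguous_senses = {
            c.cui for t, cands in inv.items() if len(cands) >= 2 for c in cands
        }
        mono_cuis = {
            cands[0].cui for t, cands in inv.items() if len(cands) == 1
        }
        expected = sum(
            1
            for g in small_world.gold
            if g.gold_cui in ambiguous_senses
            and g.gold_cui in mono_cuis
            and len(inv.lookup(g.term)) == 1
        )
        labeled = generate_pseudo_labels(small_world.documents, inv)
        assert len(labeled) == expected

    def test_vsm_backend_end_to_end_beats_random_on_small_world(self, small_world):
        labeled = generate_pseudo_labels(small_world.documents, small_world.inventory)
        if not labeled:
            pytest.skip("world has no monosemous relatives")
        cents = train_centroids(labeled)
        ann = annotate_corpus(small_world.documents, small_world.inventory,
                              VSMBackend(cents))
        prf = evaluate_wsd(ann, small_world.gold)
        assert prf.recall > 0


def test_every_backend_returns_candidate_or_abstain(small_world):
    from lbdkit.wsd import generate_pseudo_labels as gpl

    backends = [
        RandomBackend(seed=0),
        OracleBackend(small_world.gold, 0.5, seed=0),
        CollapseBackend(),
        PPRBackend(small_world.graph),
    ]
    labeled = gpl(small_world.documents, small_world.inventory)
    if labeled:
        backends.append(VSMBackend(train_centroids(labeled)))
    docs = small_world.documents[:60]
    for backend in backends:
        for ann in annotate_corpus(docs, small_world.inventory, backend):
            for a in ann.assignments:
                assert a.cui is None or a.cui in a.mention.candidate_cuis
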