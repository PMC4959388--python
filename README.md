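# lbdkit

A toolkit for **A-B-C literature-based discovery (LBD)** with pluggable
**word sense disambiguation (WSD)** and a **time-slicing** evaluation
protocol, designed to measure how WSD accuracy propagates into LBD
performance.

The pipeline:

1. **corpus** — read a dated corpus (JSON Lines, optionally PubMed XML), a
   sense inventory (term → candidate concepts), a concept relation graph,
   concept semantic types, and gold sense annotations; match inventory
   terms in titles (greedy longest-match over normalized text).
2. **wsd** — resolve each ambiguous mention with one of several backends:
   `random` (uniform baseline), `oracle` (noisy oracle at a configurable
   target accuracy), `collapse` (sense-collapsing, i.e. no WSD), `ppr`
   (personalized PageRank over the concept graph, single-pass or
   per-target), and `vsm` (sense-centroid vector space model trained on
   monosemous-relative pseudo-labels).
3. **lbd** — build the sparse title co-occurrence matrix A over assigned
   concepts (after semantic-type filtering), square it, and emit *hidden
   knowledge*: pairs nonzero in A² but zero in A, scored by the A² entry
   with the number of distinct linking concepts alongside. Open discovery
   ranks hidden pairs reachable from a source concept.
4. **evaluation** — WSD precision/recall/F against gold senses; a
   time-sliced LBD gold standard (post-cutoff co-occurrence pairs minus
   anything seen pre-cutoff); LBD precision/recall/F and scaled F
   (each system's F divided by the best F); and an oracle accuracy sweep
   tying WSD accuracy to end-to-end LBD performance.
5. **synthetic** — generator of complete, internally consistent toy worlds
   with planted A-B-C discovery triples and *ambiguity confounds*
   (an ambiguous term whose two senses bridge otherwise unrelated concepts,
   so collapsing senses manufactures spurious discoveries). Every module is
   testable offline against the generator's known ground truth.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: arithmetic
reproduction of the published F-measure column from its precision/recall
inputs, brute-force equivalence for matrix squaring and hidden-knowledge
extraction, PageRank agreement with a dense linear solve, oracle-accuracy
parameter recovery, planted-discovery recovery (and confound behaviour)
on the default synthetic world, and monotonicity of mean LBD F in oracle
accuracy.

## CLI

```sh
# generate a synthetic world (corpus, inventory, types, relations, gold)
lbdkit simulate --seed 1 --out world/

# annotate titles with a WSD backend
lbdkit annotate --corpus world/corpus.jsonl --inventory world/inventory.tsv \
    --backend ppr --relations world/relations.tsv --out ann.jsonl

# co-occurrence matrix + hidden knowledge
lbdkit discover --annotations ann.jsonl --types world/semantic_types.tsv \
    --year-start 2001 --year-end 2005 --out discovery/

# score WSD and LBD output
lbdkit eval-wsd --annotations ann.jsonl --gold world/gold.tsv --out wsd.tsv
lbdkit eval-timeslice --hidden discovery/hidden.tsv \
    --gold-annotations gold_ann.jsonl --cutoff-year 2005 --out lbd.tsv

# WSD-accuracy → LBD-performance sweep
lbdkit sweep --corpus world/corpus.jsonl --inventory world/inventory.tsv \
    --gold world/gold.tsv --cutoff-year 2005 --out sweep.tsv

# or drive the stages from one TOML config
lbdkit run --config run.toml --out results/
```

A `run.toml` for the `run` command:

```toml
[run]
corpus = "world/corpus.jsonl"
inventory = "world/inventory.tsv"
types = "world/semantic_types.tsv"
gold = "world/gold.tsv"
relations = "world/relations.tsv"
backend = "oracle"
accuracy = 1.0
cutoff_year = 2005
seed = 0
```

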