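"""Scoring: WSD precision/recall/F, time-sliced LBD gold standards, LBD
scoring with scaled F-measure, and the accuracy-sweep experiment driver."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import AnnotatedDocument, Document, GoldSenseAnnotation, SenseInventory
from .lbd import ConceptPair, CooccurrenceMatrix, build_matrix, hidden_knowledge
from .wsd import OracleBackend, annotate_corpus

__all__ = [
    "PRF",
    "TimesliceGold",
    "LBDReport",
    "f_measure",
    "evaluate_wsd",
    "build_timeslice_gold",
    "evaluate_lbd",
    "scaled_f",
    "run_accuracy_sweep",
]


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0.

    Works on fractions and on percentages alike (the formula is scale
    invariant).
    """
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class PRF:
    """Precision/recall/F with their underlying counts (fractions in [0,1]).

    ``precision_defined`` is False when nothing was attempted (precision is
    then reported as 0).
    """

    precision: float
    recall: float
    f: float
    attempted: int
    correct: int
    total: int
    precision_defined: bool = True

    @classmethod
    def from_counts(cls, correct: int, attempted: int, total: int) -> "PRF":
        if correct > attempted or correct > total:
            raise ValueError(
                f"inconsistent counts: correct={correct}, attempted={attempted}, total={total}"
            )
        defined = attempted > 0
        p = correct / attempted if defined else 0.0
        r = correct / total if total > 0 else 0.0
        return cls(
            precision=p,
            recall=r,
            f=f_measure(p, r),
            attempted=attempted,
            correct=correct,
            total=total,
            precision_defined=defined,
        )

    def percentages(self) -> tuple[float, float, float]:
        """(P, R, F) on the 0–100 scale, rounded to one decimal place."""
        return (
            round(100.0 * self.precision, 1),
            round(100.0 * self.recall, 1),
            round(100.0 * self.f, 1),
        )


def evaluate_wsd(
    predicted: Sequence[AnnotatedDocument], gold: Iterable[GoldSenseAnnotation]
) -> PRF:
    """Score predicted sense assignments against gold instances.

    Alignment is by (doc_id, char span). attempted counts non-ABSTAIN
    predictions aligned to a gold instance; total is the number of gold
    instances.
    """
    gold_by_key = {g.key: g.gold_cui for g in gold}
    if not gold_by_key:
        raise ValueError("evaluate_wsd: empty gold standard")
    attempted = 0
    correct = 0
    for doc in predicted:
        for a in doc.assignments:
            key = (doc.doc_id, a.mention.start, a.mention.end)
            if key not in gold_by_key or a.cui is None:
                continue
            attempted += 1
            if a.cui == gold_by_key[key]:
                correct += 1
    return PRF.from_counts(correct=correct, attempted=attempted, total=len(gold_by_key))


@dataclass(frozen=True)
class TimesliceGold:
    """Concept pairs first co-occurring after the cutoff year."""

    cutoff_year: int
    pairs: frozenset[tuple[str, str]]
    n_post_docs: int
    n_eliminated: int


def _title_pairs(doc: AnnotatedDocument) -> set[tuple[str, str]]:
    cuis = sorted(set(doc.assigned_cuis()))
    return {
        (cuis[i], cuis[j])
        for i in range(len(cuis))
        for j in range(i + 1, len(cuis))
    }


def build_timeslice_gold(
    annotated: Sequence[AnnotatedDocument], cutoff_year: int
) -> TimesliceGold:
    """Post-cutoff co-occurrence pairs minus any pair seen up to the cutoff.

    ``year <= cutoff_year`` is "pre", ``year > cutoff_year`` is "post".
    """
    pre_pairs: set[tuple[str, str]] = set()
    post_pairs: set[tuple[str, str]] = set()
    n_post = 0
    for doc in annotated:
        pairs = _title_pairs(doc)
        if doc.year > cutoff_year:
            post_pairs |= pairs
            n_post += 1
        else:
            pre_pairs |= pairs
    if n_post == 0:
        raise ValueError(f"no documents after cutoff year {cutoff_year}")
    gold = post_pairs - pre_pairs
    return TimesliceGold(
        cutoff_year=cutoff_year,
        pairs=frozenset(gold),
        n_post_docs=n_post,
        n_eliminated=len(post_pairs) - len(gold),
    )


def evaluate_lbd(hidden: Iterable[ConceptPair], gold: TimesliceGold) -> PRF:
    """Score hidden-knowledge pairs against a timeslice gold standard."""
    if not gold.pairs:
        raise ValueError("evaluate_lbd: empty gold standard")
    hidden_keys = {p.key for p in hidden}
    correct = len(hidden_keys & gold.pairs)
    return PRF.from_counts(correct=correct, attempted=len(hidden_keys), total=len(gold.pairs))


@dataclass(frozen=True)
class LBDReport:
    label: str
    n_hidden: int
    prf: PRF
    scaled_f: float | None = None


def scaled_f(reports: Sequence[LBDReport]) -> list[LBDReport]:
    """Divide every F by the best system's F; the reference scores exactly 1."""
    if not reports:
        raise ValueError("scaled_f: no reports")
    f_ref = max(r.prf.f for r in reports)
    if f_ref == 0:
        raise ValueError("scaled_f: all F-measures are zero")
    out = []
    for r in reports:
        value = 1.0 if r.prf.f == f_ref else r.prf.f / f_ref
        out.append(replace(r, scaled_f=value))
    return out


def run_accuracy_sweep(
    docs: Sequence[Document],
    inventory: SenseInventory,
    gold: Sequence[GoldSenseAnnotation],
    accuracies: Sequence[float],
    seeds: Sequence[int],
    cutoff_year: int,
    type_map: Mapping[str, set[str]] | None = None,
    excluded_types: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Oracle-accuracy sweep over the full LBD pipeline.

    For each (accuracy, seed) pair: annotate the pre-cutoff documents with
    the noisy oracle at that target accuracy, build the co-occurrence matrix,
    extract hidden knowledge, and score it against the timeslice gold built
    from gold-sense annotations of the full timeline. Returns per-run rows
    and per-accuracy means.
    """
    if any(not 0.0 <= a <= 1.0 for a in accuracies):
        raise ValueError("accuracies must lie in [0, 1]")
    years = [d.year for d in docs]
    if min(years) > cutoff_year or max(years) <= cutoff_year:
        raise ValueError("corpus does not span the cutoff year")

    # reference annotation (oracle at accuracy 1.0 == gold) defines the
    # timeslice gold standard and the WSD scoring target
    gold_backend = OracleBackend(gold, target_accuracy=1.0, seed=0)
    gold_annotated = annotate_corpus(docs, inventory, gold_backend)
    timeslice = build_timeslice_gold(gold_annotated, cutoff_year)

    pre_docs = [d for d in docs if d.year <= cutoff_year]
    year_range = (min(years), cutoff_year)

    rows = []
    for accuracy in accuracies:
        for seed in seeds:
            backend = OracleBackend(gold, target_accuracy=accuracy, seed=seed)
            annotated = annotate_corpus(pre_docs, inventory, backend)
            wsd_prf = evaluate_wsd(annotated, gold)
            matrix = build_matrix(
                annotated,
                type_map=type_map,
                excluded_types=excluded_types,
                year_range=year_range,
            )
            hidden = hidden_knowledge(matrix)
            lbd_prf = evaluate_lbd(hidden, timeslice)
            rows.append(
                {
                    "target_accuracy": accuracy,
                    "seed": seed,
                    "measured_accuracy": wsd_prf.precision,
                    "precision": lbd_prf.precision,
                    "recall": lbd_prf.recall,
                    "f": lbd_prf.f,
                    "n_hidden": len(hidden),
                }
            )
    table = pd.DataFrame(rows)
    means = (
        table.drop(columns="seed")
        .groupby("target_accuracy", sort=False)
        .mean()
        .reset_index()
    )
    f_ref = means["f"].max()
    if f_ref > 0:
        table["scaled_f"] = table["f"] / f_ref
        means["scaled_f"] = means["f"] / f_ref
    else:
        table["scaled_f"] = 0.0
        means["scaled_f"] = 0.0
    return table, means
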