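"""Symptom co-occurrence graph, association scoring, and top-K recommendation.

Symptoms, like words, are known by the company they keep: two symptoms that
frequently co-occur in patient records suggest each other's presence. The graph
counts, for every unordered pair of distinct status-true symptoms in a record,
one co-occurrence. The directional association of symptom ``s_i`` with ``s_j``
is the pair count normalized by ``s_i``'s row total, so each nonzero row forms
a probability distribution over companions.

The recommender ranks every unconfirmed symptom by its summed association from
the confirmed set (anchor-row normalization) and returns the K best; this is
the ARM recommendation surfaced in the dialogue state and rewarded by the
recommendation critic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable

import numpy as np

from .dataset import DiagnosisDataset

__all__ = [
    "CooccurrenceGraph",
    "Recommendation",
    "UnknownSymptomError",
    "build_cooccurrence",
    "association_score",
    "context_association",
    "recommend_top_k",
    "save_graph",
    "load_graph",
]


class UnknownSymptomError(KeyError):
    """Symptom identifier not present in the graph's vocabulary."""


@dataclass(frozen=True)
class Recommendation:
    """Top-K recommended symptoms with their summed association scores.

    Scores are non-increasing; recommended symptoms are never already
    confirmed.
    """

    symptoms: tuple[str, ...]
    scores: tuple[float, ...]

    def __contains__(self, symptom: str) -> bool:
        return symptom in self.symptoms


class CooccurrenceGraph:
    """Symmetric co-occurrence counts over a fixed symptom vocabulary.

    ``counts[i, j]`` is the number of records in which symptoms i and j both
    hold true; the diagonal is zero (a symptom is not its own companion).
    """

    def __init__(self, symptom_index: list[str], counts: np.ndarray):
        counts = np.asarray(counts, dtype=np.int64)
        n = len(symptom_index)
        if counts.shape != (n, n):
            raise ValueError("counts must be square over the symptom vocabulary")
        if np.any(counts < 0):
            raise ValueError("co-occurrence counts must be nonnegative")
        if np.any(counts != counts.T):
            raise ValueError("co-occurrence counts must be symmetric")
        if np.any(np.diag(counts) != 0):
            raise ValueError("co-occurrence diagonal must be zero")
        self.symptom_index = list(symptom_index)
        self.counts = counts
        self._pos = {s: i for i, s in enumerate(self.symptom_index)}
        self.row_totals = counts.sum(axis=1)

    def index_of(self, symptom: str) -> int:
        try:
            return self._pos[symptom]
        except KeyError:
            raise UnknownSymptomError(symptom) from None

    def __len__(self) -> int:
        return len(self.symptom_index)


def build_cooccurrence(dataset: DiagnosisDataset) -> CooccurrenceGraph:
    """Count co-occurrences of status-true symptoms (explicit + implicit) per record.

    False and unknown statuses never contribute; a record with fewer than two
    true symptoms contributes nothing.
    """
    if not dataset.records:
        raise ValueError("cannot build a co-occurrence graph from an empty dataset")
    n = len(dataset.symptom_vocabulary)
    pos = {s: i for i, s in enumerate(dataset.symptom_vocabulary)}
    counts = np.zeros((n, n), dtype=np.int64)
    for rec in dataset.records:
        idx = sorted(pos[s] for s in rec.true_symptoms())
        for i, j in combinations(idx, 2):
            counts[i, j] += 1
            counts[j, i] += 1
    return CooccurrenceGraph(dataset.symptom_vocabulary, counts)


def association_score(graph: CooccurrenceGraph, s_i: str, s_j: str) -> float:
    """Directional association of ``s_i`` with ``s_j``: n(i,j) / row_total(i).

    A symptom that never co-occurs with anything scores 0 with every partner
    (zero-row smoothing rather than an error).
    """
    i = graph.index_of(s_i)
    j = graph.index_of(s_j)
    total = graph.row_totals[i]
    if total == 0:
        return 0.0
    return float(graph.counts[i, j]) / float(total)


def context_association(
    graph: CooccurrenceGraph, queried: str, confirmed: Iterable[str]
) -> float:
    """Summed association of the queried symptom with each confirmed anchor.

    This is the association critic's input: the relevance of the currently
    requested symptom to the confirmed set (self-report included). Empty
    confirmed set gives 0. Note the queried symptom's row supplies the
    normalizer (queried-first argument order).
    """
    return float(sum(association_score(graph, queried, c) for c in confirmed))


def recommend_top_k(
    graph: CooccurrenceGraph, confirmed: Iterable[str], k: int
) -> Recommendation:
    """Rank unconfirmed symptoms by summed association *from* the confirmed anchors.

    Candidate s scores sum_j Association(confirmed_j, s) — each anchor's row
    normalizes its own contribution. Ties break by vocabulary index (ascending).
    With an empty confirmed set the ranking falls back to global co-occurrence
    frequency (row totals). If k exceeds the remaining vocabulary, all remaining
    symptoms are returned, ranked.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    confirmed = list(confirmed)
    conf_idx = [graph.index_of(c) for c in confirmed]
    n = len(graph)
    if conf_idx:
        scores = np.zeros(n, dtype=float)
        for i in conf_idx:
            total = graph.row_totals[i]
            if total > 0:
                scores += graph.counts[i].astype(float) / float(total)
    else:
        scores = graph.row_totals.astype(float)
    mask = np.ones(n, dtype=bool)
    mask[conf_idx] = False
    candidates = np.nonzero(mask)[0]
    # sort by descending score, then ascending vocabulary index
    order = candidates[np.lexsort((candidates, -scores[candidates]))]
    top = order[:k]
    return Recommendation(
        symptoms=tuple(graph.symptom_index[i] for i in top),
        scores=tuple(float(scores[i]) for i in top),
    )


def save_graph(graph: CooccurrenceGraph, path: str | Path) -> None:
    """Persist as JSON: vocabulary plus sparse upper-triangle count triples."""
    i_idx, j_idx = np.nonzero(np.triu(graph.counts, k=1))
    obj = {
        "symptoms": graph.symptom_index,
        "counts": [
            [int(i), int(j), int(graph.counts[i, j])] for i, j in zip(i_idx, j_idx)
        ],
    }
    Path(path).write_text(
        json.dumps(obj, sort_keys=True, separators=(",", ":")) + "\n", encoding="utf-8"
    )


def load_graph(path: str | Path) -> CooccurrenceGraph:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    symptoms = obj["symptoms"]
    n = len(symptoms)
    counts = np.zeros((n, n), dtype=np.int64)
    for i, j, c in obj["counts"]:
        counts[i, j] = c
        counts[j, i] = c
    return CooccurrenceGraph(symptoms, counts)
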