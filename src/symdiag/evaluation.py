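"""Dialogue-level evaluation metrics.

All metrics are pure functions of episode logs (plus the association graph for
the relevance scores), so any serialized JSONL episode set can be re-scored
offline.

* success rate — fraction of dialogues ending with the correct disease;
* average dialogue turn — mean number of agent symptom queries;
* average reward — mean per-episode summed shaped reward;
* AMR — mean over dialogues of (queries answered true) / (queries), x100;
* AMR2 — mean of (queries answered true) / (patient's true implicit count), x100;
* IReS-1 / IReS-2 — Investigation Relevance Score: the average, per query
  turn, of the queried symptom's summed association with the patient
  self-report (IReS-1) or with the full confirmed set at the moment of the
  query (IReS-2). IReS-2 can exceed 1 because the anchor set grows;
* top-k disease coverage — fraction of dialogues whose true disease appears in
  the classifier's top-k ranking, x100;
* group confusion — for failed dialogues, true group vs. predicted disease's
  group; the diagonal is "right department, wrong disease", which dominates
  when diseases inside a group share symptoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import CooccurrenceGraph, association_score
from .environment import EpisodeLog

__all__ = [
    "MetricsReport",
    "Transcript",
    "success_rate",
    "avg_turns",
    "avg_reward",
    "match_rates",
    "ires",
    "topk_disease_coverage",
    "group_confusion",
    "compute_metrics",
    "score_transcript",
    "load_transcripts",
]


def success_rate(episodes: Sequence[EpisodeLog]) -> float:
    if not episodes:
        raise ValueError("no episodes")
    return float(np.mean([e.success for e in episodes]))


def avg_turns(episodes: Sequence[EpisodeLog]) -> float:
    if not episodes:
        raise ValueError("no episodes")
    return float(np.mean([e.turns for e in episodes]))


def avg_reward(episodes: Sequence[EpisodeLog]) -> float:
    if not episodes:
        raise ValueError("no episodes")
    return float(np.mean([e.total_reward for e in episodes]))


def match_rates(episodes: Sequence[EpisodeLog]) -> tuple[Optional[float], Optional[float]]:
    """(AMR, AMR2) as percentages.

    AMR averages m_i / r_i (true answers per query) over episodes with at
    least one query; AMR2 averages m_i / t_i (true answers per true implicit
    symptom) over episodes with at least one true implicit symptom. Episodes
    failing the respective zero-guard are excluded from that mean; a metric
    with no eligible episode is None.
    """
    if not episodes:
        raise ValueError("no episodes")
    mr, mr2 = [], []
    for e in episodes:
        m = sum(1 for q in e.queries if q.answer)
        if e.turns > 0:
            mr.append(m / e.turns)
        if e.n_implicit_true > 0:
            mr2.append(m / e.n_implicit_true)
    amr = float(np.mean(mr)) * 100.0 if mr else None
    amr2 = float(np.mean(mr2)) * 100.0 if mr2 else None
    return amr, amr2


def _relevance_sums(
    self_report: Sequence[str],
    queries: Sequence[tuple[str, bool]],
    graph: CooccurrenceGraph,
) -> tuple[float, float, int]:
    """(IReS-1 numerator, IReS-2 numerator, query-turn count) for one dialogue.

    The IReS-2 anchor set is the confirmed set *before* each turn's answer is
    applied, so a query never anchors itself; repeated queries still count as
    turns the patient experienced.
    """
    psr = list(self_report)
    confirmed = set(psr)
    num1 = num2 = 0.0
    for symptom, answer in queries:
        num1 += sum(association_score(graph, symptom, a) for a in psr)
        num2 += sum(association_score(graph, symptom, a) for a in confirmed)
        if answer:
            confirmed.add(symptom)
    return num1, num2, len(queries)


def ires(
    episodes: Sequence[EpisodeLog], graph: CooccurrenceGraph
) -> tuple[Optional[float], Optional[float]]:
    """(IReS-1, IReS-2): per-query-turn averaged anchor association sums.

    None when the episode set contains no query turns at all.
    """
    if not episodes:
        raise ValueError("no episodes")
    num1 = num2 = 0.0
    turns = 0
    for e in episodes:
        n1, n2, n = _relevance_sums(
            e.self_report, [(q.symptom, q.answer) for q in e.queries], graph
        )
        num1 += n1
        num2 += n2
        turns += n
    if turns == 0:
        return None, None
    return num1 / turns, num2 / turns


def topk_disease_coverage(episodes: Sequence[EpisodeLog], k: int) -> float:
    """Percentage of episodes whose true disease is in the top-k ranking."""
    ranked = [e for e in episodes if e.disease_ranking is not None]
    if not ranked:
        raise ValueError("no episodes carrying a disease ranking")
    hits = [e.true_disease in e.disease_ranking[:k] for e in ranked]
    return float(np.mean(hits)) * 100.0


def group_confusion(
    episodes: Sequence[EpisodeLog], group_map: dict[str, str], groups: Sequence[str]
) -> pd.DataFrame:
    """Failed-episode counts: rows = true group, columns = predicted disease's group.

    Turn-limit episodes without a predicted disease are not counted (there is
    no predicted group to attribute the failure to).
    """
    table = pd.DataFrame(0, index=list(groups), columns=list(groups), dtype=int)
    for e in episodes:
        if e.success or e.predicted_disease is None:
            continue
        table.loc[group_map[e.true_disease], group_map[e.predicted_disease]] += 1
    return table


@dataclass
class MetricsReport:
    """Every reported metric for one episode set."""

    n_episodes: int
    success_rate: float
    avg_reward: float
    avg_turns: float
    amr: Optional[float]
    amr2: Optional[float]
    ires1: Optional[float]
    ires2: Optional[float]
    coverage: dict[int, Optional[float]] = field(default_factory=dict)
    dc_accuracy: Optional[float] = None
    group_confusion: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        return {
            "n_episodes": self.n_episodes,
            "success_rate": self.success_rate,
            "avg_reward": self.avg_reward,
            "avg_turns": self.avg_turns,
            "amr": self.amr,
            "amr2": self.amr2,
            "ires1": self.ires1,
            "ires2": self.ires2,
            "coverage": {str(k): v for k, v in self.coverage.items()},
            "dc_accuracy": self.dc_accuracy,
            "group_confusion": (
                None if self.group_confusion is None
                else self.group_confusion.to_dict()
            ),
        }

    def to_csv_row(self) -> pd.DataFrame:
        flat = {k: v for k, v in self.to_dict().items()
                if k not in ("coverage", "group_confusion")}
        for k, v in self.coverage.items():
            flat[f"top{k}_coverage"] = v
        return pd.DataFrame([flat])


def compute_metrics(
    episodes: Sequence[EpisodeLog],
    graph: CooccurrenceGraph,
    group_map: Optional[dict[str, str]] = None,
    groups: Optional[Sequence[str]] = None,
    ks: Sequence[int] = (3, 5),
    dc_accuracy: Optional[float] = None,
) -> MetricsReport:
    """Assemble the full report from episode logs."""
    amr, amr2 = match_rates(episodes)
    i1, i2 = ires(episodes, graph)
    coverage: dict[int, Optional[float]] = {}
    for k in ks:
        try:
            coverage[k] = topk_disease_coverage(episodes, k)
        except ValueError:
            coverage[k] = None
    confusion = None
    if group_map is not None and groups is not None:
        confusion = group_confusion(episodes, group_map, groups)
    return MetricsReport(
        n_episodes=len(episodes),
        success_rate=success_rate(episodes),
        avg_reward=avg_reward(episodes),
        avg_turns=avg_turns(episodes),
        amr=amr,
        amr2=amr2,
        ires1=i1,
        ires2=i2,
        coverage=coverage,
        dc_accuracy=dc_accuracy,
        group_confusion=confusion,
    )


@dataclass(frozen=True)
class Transcript:
    """A fixed dialogue: self-report, (query, answer) pairs, and the outcome labels."""

    self_report: tuple[str, ...]
    queries: tuple[tuple[str, bool], ...]
    true_disease: Optional[str] = None
    predicted_disease: Optional[str] = None
    name: Optional[str] = None


def load_transcripts(path: str | Path) -> list[Transcript]:
    """Read a JSON transcript fixture file (a list of transcript objects)."""
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for raw in obj:
        out.append(Transcript(
            self_report=tuple(raw["self_report"]),
            queries=tuple((s, bool(a)) for s, a in raw["queries"]),
            true_disease=raw.get("true_disease"),
            predicted_disease=raw.get("predicted_disease"),
            name=raw.get("name"),
        ))
    return out


def score_transcript(transcript: Transcript, graph: CooccurrenceGraph) -> dict:
    """Turns, match rate and IReS-1/2 for one fixed dialogue.

    An empty transcript reports zero turns and absent (None) rates.
    """
    n = len(transcript.queries)
    if n == 0:
        return {"turns": 0, "match_rate": None, "ires1": None, "ires2": None,
                "success": None}
    matches = sum(1 for _, a in transcript.queries if a)
    num1, num2, turns = _relevance_sums(
        transcript.self_report, transcript.queries, graph
    )
    success = None
    if transcript.true_disease is not None and transcript.predicted_disease is not None:
        success = transcript.predicted_disease == transcript.true_disease
    return {
        "turns": turns,
        "match_rate": matches / n,
        "ires1": num1 / turns,
        "ires2": num2 / turns,
        "success": success,
    }
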