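"""Simulated patient, dialogue state tracking, and the policy state encoding.

The patient simulator answers symptom queries from a sampled diagnosis case:
recorded symptoms answer with their recorded status, anything else is a denial
(the standard goal-oriented simulator convention). The state tracker holds a
three-valued status per symptom (true / false / unknown), the turn counter,
the last agent action, the current ARM recommendations and the last shaped
reward; statuses only ever move unknown -> known within an episode.

State encoding layout over a vocabulary of n symptoms (documented, fixed):

====================  =========================================
``[0, 3n)``           per-symptom status triple (true, false, unknown)
``[3n, 4n)``          one-hot of the last symptom query (zeros if none)
``[4n, 5n)``          K-hot of the currently recommended symptoms
``[5n]``              turn / N (normalized turn counter)
``[5n + 1]``          last shaped reward / reward_scale
====================  =========================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .association import CooccurrenceGraph, Recommendation, recommend_top_k
from .dataset import PatientRecord

__all__ = [
    "DialogueState",
    "QueryOutcome",
    "EpisodeLog",
    "EpisodeTerminatedError",
    "reset",
    "respond",
    "step",
    "encode_state",
    "encode_symptom_status",
    "write_episode_logs",
    "read_episode_logs",
]

STATUS_UNKNOWN = 0
STATUS_TRUE = 1
STATUS_FALSE = 2


class EpisodeTerminatedError(RuntimeError):
    """Raised when stepping an episode that has already hit its turn limit."""


@dataclass
class DialogueState:
    """Tracked dialogue state; backed by a compact status array for fast encoding."""

    vocabulary: list[str]
    status: np.ndarray  # int8 codes, one per vocabulary symptom
    turn: int = 0
    last_agent_action: Optional[str] = None
    recommended: Optional[Recommendation] = None
    last_reward: float = 0.0
    _pos: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._pos:
            self._pos = {s: i for i, s in enumerate(self.vocabulary)}

    @property
    def symptom_status(self) -> dict[str, Optional[bool]]:
        """Status map view: True / False / None (unknown)."""
        lut = {STATUS_UNKNOWN: None, STATUS_TRUE: True, STATUS_FALSE: False}
        return {s: lut[int(self.status[i])] for i, s in enumerate(self.vocabulary)}

    @property
    def confirmed_set(self) -> set[str]:
        """Status-true symptoms (SS), self-report included."""
        return {self.vocabulary[i] for i in np.nonzero(self.status == STATUS_TRUE)[0]}

    def status_of(self, symptom: str) -> Optional[bool]:
        code = int(self.status[self._pos[symptom]])
        return {STATUS_UNKNOWN: None, STATUS_TRUE: True, STATUS_FALSE: False}[code]


@dataclass(frozen=True)
class QueryOutcome:
    """One agent query with the patient's answer and the three critic rewards."""

    symptom: str
    answer: bool
    r_d: float
    r_rr: float
    r_ar: float

    @property
    def total(self) -> float:
        return self.r_d + self.r_rr + self.r_ar


@dataclass
class EpisodeLog:
    """Full record of one simulated dialogue; the substrate of every metric."""

    record_id: str
    self_report: list[str]
    true_disease: str
    queries: list[QueryOutcome] = field(default_factory=list)
    department_activations: list[str] = field(default_factory=list)
    predicted_disease: Optional[str] = None
    disease_ranking: Optional[list[str]] = None
    success: bool = False
    terminated_by: str = "diagnosis"
    terminal_reward: float = 0.0
    n_implicit_true: int = 0

    @property
    def turns(self) -> int:
        return len(self.queries)

    @property
    def total_reward(self) -> float:
        return sum(q.total for q in self.queries) + self.terminal_reward


def reset(record: PatientRecord, graph: CooccurrenceGraph, k: int) -> DialogueState:
    """Start an episode: explicit symptoms take their recorded status, rest unknown."""
    vocab = graph.symptom_index
    status = np.zeros(len(vocab), dtype=np.int8)
    state = DialogueState(vocabulary=vocab, status=status)
    for s, v in record.explicit_symptoms.items():
        state.status[state._pos[s]] = STATUS_TRUE if v else STATUS_FALSE
    state.recommended = recommend_top_k(graph, state.confirmed_set, k)
    return state


def respond(record: PatientRecord, queried: str) -> bool:
    """Patient answer: recorded status if the symptom is in the case, else a denial."""
    status = record.symptom_status()
    if queried in status:
        return status[queried]
    return False


def step(
    state: DialogueState,
    record: PatientRecord,
    queried: str,
    graph: CooccurrenceGraph,
    k: int,
    max_turns: int = 28,
) -> tuple[DialogueState, bool, bool, bool]:
    """Apply one agent query in place.

    Returns ``(state, answer, repetition_flag, turn_limit_flag)``. A repetition
    (status already known) leaves statuses unchanged; the penalty is the
    internal critic's business, not the environment's. The turn counter always
    advances and recommendations are recomputed from the updated confirmed set.
    The caller is responsible for setting ``state.last_reward`` once the critics
    have scored the query.
    """
    if state.turn >= max_turns:
        raise EpisodeTerminatedError("episode already reached the turn limit")
    pos = state._pos[queried]
    repetition = int(state.status[pos]) != STATUS_UNKNOWN
    answer = respond(record, queried)
    if not repetition:
        state.status[pos] = STATUS_TRUE if answer else STATUS_FALSE
    state.turn += 1
    state.last_agent_action = queried
    state.recommended = recommend_top_k(graph, state.confirmed_set, k)
    return state, answer, repetition, state.turn >= max_turns


def encode_symptom_status(status: np.ndarray) -> np.ndarray:
    """3n one-hot status encoding (true, false, unknown per symptom)."""
    n = len(status)
    out = np.zeros(3 * n, dtype=np.float64)
    out[0::3] = status == STATUS_TRUE
    out[1::3] = status == STATUS_FALSE
    out[2::3] = status == STATUS_UNKNOWN
    return out


def encode_state(
    state: DialogueState,
    vocabulary: Sequence[str],
    max_turns: int = 28,
    reward_scale: float = 114.0,
) -> np.ndarray:
    """Fixed-layout feature vector of length 5n + 2 (see module docstring)."""
    n = len(vocabulary)
    vec = np.zeros(5 * n + 2, dtype=np.float64)
    vec[: 3 * n] = encode_symptom_status(state.status)
    if state.last_agent_action is not None:
        i = state._pos.get(state.last_agent_action)
        if i is not None:
            vec[3 * n + i] = 1.0
    if state.recommended is not None:
        for s in state.recommended.symptoms:
            vec[4 * n + state._pos[s]] = 1.0
    vec[5 * n] = state.turn / max_turns
    vec[5 * n + 1] = state.last_reward / reward_scale
    return vec


def _log_to_obj(log: EpisodeLog) -> dict:
    return {
        "record_id": log.record_id,
        "self_report": list(log.self_report),
        "true_disease": log.true_disease,
        "queries": [
            [q.symptom, q.answer, q.r_d, q.r_rr, q.r_ar] for q in log.queries
        ],
        "department_activations": list(log.department_activations),
        "predicted_disease": log.predicted_disease,
        "disease_ranking": log.disease_ranking,
        "success": log.success,
        "terminated_by": log.terminated_by,
        "terminal_reward": log.terminal_reward,
        "n_implicit_true": log.n_implicit_true,
    }


def write_episode_logs(logs: Sequence[EpisodeLog], path: str | Path) -> None:
    """One JSON object per line (JSONL)."""
    with open(path, "w", encoding="utf-8") as fh:
        for log in logs:
            fh.write(json.dumps(_log_to_obj(log), sort_keys=True) + "\n")


def read_episode_logs(path: str | Path) -> list[EpisodeLog]:
    logs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            logs.append(EpisodeLog(
                record_id=obj["record_id"],
                self_report=list(obj["self_report"]),
                true_disease=obj["true_disease"],
                queries=[QueryOutcome(s, bool(a), rd, rr, ar)
                         for s, a, rd, rr, ar in obj["queries"]],
                department_activations=list(obj["department_activations"]),
                predicted_disease=obj["predicted_disease"],
                disease_ranking=obj["disease_ranking"],
                success=bool(obj["success"]),
                terminated_by=obj["terminated_by"],
                terminal_reward=float(obj["terminal_reward"]),
                n_implicit_true=int(obj["n_implicit_true"]),
            ))
    return logs
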