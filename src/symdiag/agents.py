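"""Q-learning policies and the two-level investigation agent.

The controller policy chooses a medical department (one worker per disease
group) or the diagnose action; an activated departmental worker queries
symptoms from its own group's symptom set until it returns control or the
global turn limit hits. Workers are rewarded per turn by the internal critic
plus the two ARM critics; the controller's reward for a department activation
is the discounted sum of the subtask's internal rewards, and the raw terminal
reward when it diagnoses. Both levels learn with DQN (or Double DQN) over a
replay buffer with a periodically synchronized target network and epsilon-
greedy exploration.
"""

from __future__ import annotations

import pickle
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .association import CooccurrenceGraph, context_association
from .classifier import DiseaseClassifier, predict_disease
from .dataset import DiagnosisDataset, PatientRecord
from .environment import (
    DialogueState,
    EpisodeLog,
    QueryOutcome,
    encode_state,
    encode_symptom_status,
    reset,
    step,
)
from .nn import MLP
from .rewards import (
    RewardConfig,
    association_reward,
    controller_reward,
    internal_reward,
    recommendation_reward,
    total_reward,
)

__all__ = [
    "Transition",
    "ReplayBuffer",
    "QPolicy",
    "AgentConfig",
    "HierarchicalAgent",
    "FlatPolicyAgent",
    "q_values",
    "select_action",
    "td_targets",
    "train_step",
    "sync_target",
    "department_symptoms",
    "run_scripted_episode",
    "train",
    "evaluate_agent",
    "save_agent",
    "load_agent",
]


@dataclass(frozen=True)
class Transition:
    """(state, action, reward, next state, terminal) replay unit."""

    state: np.ndarray
    action: int
    reward: float
    next_state: np.ndarray
    terminal: bool


class ReplayBuffer:
    """Bounded FIFO store of transitions with uniform sampling."""

    def __init__(self, capacity: int):
        self._buf: deque[Transition] = deque(maxlen=capacity)

    def push(self, transition: Transition) -> None:
        self._buf.append(transition)

    def sample(self, batch_size: int, rng: np.random.Generator) -> list[Transition]:
        idx = rng.integers(0, len(self._buf), size=batch_size)
        return [self._buf[i] for i in idx]

    def __len__(self) -> int:
        return len(self._buf)


class QPolicy:
    """A value network with a frozen target twin, replay buffer and action space."""

    def __init__(
        self,
        action_space: Sequence[str],
        n_inputs: int,
        hidden: int,
        epsilon: float,
        gamma: float,
        mode: str,
        replay_capacity: int,
        lr: float,
        rng: np.random.Generator,
    ):
        if mode not in ("dqn", "ddqn"):
            raise ValueError("mode must be 'dqn' or 'ddqn'")
        self.action_space = list(action_space)
        self.net = MLP(n_inputs, hidden, len(self.action_space), rng)
        self.target_net = self.net.clone()
        self.epsilon = epsilon
        self.gamma = gamma
        self.mode = mode
        self.lr = lr
        self.replay = ReplayBuffer(replay_capacity)

    @property
    def n_inputs(self) -> int:
        return self.net.n_in


def q_values(policy: QPolicy, state_vector: np.ndarray, target: bool = False) -> np.ndarray:
    """Per-action values for one state; deterministic for fixed parameters."""
    state_vector = np.asarray(state_vector, dtype=np.float64)
    if state_vector.shape != (policy.n_inputs,):
        raise ValueError(
            f"state vector length {state_vector.shape} does not match "
            f"policy input size {policy.n_inputs}"
        )
    net = policy.target_net if target else policy.net
    return net.forward(state_vector)[0]


def select_action(
    values: np.ndarray,
    epsilon: float,
    mask: Optional[np.ndarray],
    rng: np.random.Generator,
) -> int:
    """Epsilon-greedy over allowed actions; greedy ties break to the lowest index."""
    values = np.asarray(values, dtype=np.float64)
    if mask is None:
        mask = np.ones(len(values), dtype=bool)
    allowed = np.nonzero(mask)[0]
    if len(allowed) == 0:
        raise ValueError("no allowed action")
    if epsilon > 0.0 and rng.random() < epsilon:
        return int(allowed[rng.integers(0, len(allowed))])
    best = allowed[np.argmax(values[allowed])]
    return int(best)


def td_targets(
    batch: Sequence[Transition], policy: QPolicy, mode: Optional[str] = None
) -> np.ndarray:
    """Bootstrapped TD targets: r for terminals, else r + gamma * bootstrap(s').

    DQN bootstraps with the target network's own maximum; Double DQN evaluates
    the behavior network's argmax under the target network, decoupling action
    selection from value estimation.
    """
    if not batch:
        raise ValueError("batch must be nonempty")
    mode = mode or policy.mode
    next_states = np.stack([t.next_state for t in batch])
    rewards = np.array([t.reward for t in batch])
    terminal = np.array([t.terminal for t in batch])
    q_next_target = policy.target_net.forward(next_states)
    if mode == "dqn":
        bootstrap = q_next_target.max(axis=1)
    elif mode == "ddqn":
        greedy = policy.net.forward(next_states).argmax(axis=1)
        bootstrap = q_next_target[np.arange(len(batch)), greedy]
    else:
        raise ValueError("mode must be 'dqn' or 'ddqn'")
    return np.where(terminal, rewards, rewards + policy.gamma * bootstrap)


def train_step(policy: QPolicy, batch: Sequence[Transition]) -> float:
    """One gradient update of the behavior net on the batch's TD error."""
    if not batch:
        raise ValueError("batch must be nonempty")
    targets = td_targets(batch, policy)
    X = np.stack([t.state for t in batch])
    actions = np.array([t.action for t in batch])
    return policy.net.sgd_q_step(X, actions, targets, policy.lr)


def sync_target(policy: QPolicy) -> None:
    """Copy behavior parameters into the target network."""
    policy.target_net.set_params(policy.net.get_params())


@dataclass(frozen=True)
class AgentConfig:
    """Architecture and learning hyperparameters.

    Defaults follow the benchmark setup where stated (learning rate 5e-4,
    batch 100, epsilon 0.1 without annealing); hidden width, replay capacity,
    target-sync cadence and update count are stability choices. ``k`` is the
    ARM recommendation breadth. ``mask_known_eval`` masks already-answered
    symptom actions during greedy evaluation only, leaving the repetition
    penalty learnable during training.
    """

    hidden: int = 512
    lr: float = 5e-4
    batch_size: int = 100
    replay_capacity: int = 10000
    epsilon: float = 0.1
    mode: str = "dqn"
    k: int = 5
    updates_per_epoch: int = 5
    sync_every: int = 1
    mask_known_eval: bool = True


def department_symptoms(dataset: DiagnosisDataset) -> dict[str, list[str]]:
    """Symptoms observed (any status) in each group's records, vocabulary-ordered."""
    pos = {s: i for i, s in enumerate(dataset.symptom_vocabulary)}
    sets: dict[str, set[str]] = {g: set() for g in dataset.groups}
    for rec in dataset.records:
        sets[rec.group].update(rec.explicit_symptoms)
        sets[rec.group].update(rec.implicit_symptoms)
    return {g: sorted(s, key=pos.__getitem__) for g, s in sets.items()}


class HierarchicalAgent:
    """Controller over departments + diagnose; one worker policy per disease group."""

    DIAGNOSE = "diagnose"
    RETURN = "return_control"

    def __init__(
        self,
        dataset: DiagnosisDataset,
        graph: CooccurrenceGraph,
        classifier: DiseaseClassifier,
        reward_cfg: RewardConfig,
        agent_cfg: AgentConfig,
        rng: np.random.Generator,
    ):
        self.graph = graph
        self.classifier = classifier
        self.reward_cfg = reward_cfg
        self.agent_cfg = agent_cfg
        self.groups = dataset.groups
        self.dept_symptoms = department_symptoms(dataset)
        n_in = 5 * len(graph.symptom_index) + 2
        self.controller = QPolicy(
            action_space=self.groups + [self.DIAGNOSE],
            n_inputs=n_in,
            hidden=agent_cfg.hidden,
            epsilon=agent_cfg.epsilon,
            gamma=reward_cfg.gamma_c,
            mode=agent_cfg.mode,
            replay_capacity=agent_cfg.replay_capacity,
            lr=agent_cfg.lr,
            rng=rng,
        )
        self.departments: dict[str, QPolicy] = {}
        for g in self.groups:
            self.departments[g] = QPolicy(
                action_space=self.dept_symptoms[g] + [self.RETURN],
                n_inputs=n_in,
                hidden=agent_cfg.hidden,
                epsilon=agent_cfg.epsilon,
                gamma=reward_cfg.gamma_w,
                mode=agent_cfg.mode,
                replay_capacity=agent_cfg.replay_capacity,
                lr=agent_cfg.lr,
                rng=rng,
            )

    @property
    def policies(self) -> list[QPolicy]:
        return [self.controller] + [self.departments[g] for g in self.groups]

    def _encode(self, state: DialogueState) -> np.ndarray:
        return encode_state(
            state,
            self.graph.symptom_index,
            max_turns=self.reward_cfg.N,
            reward_scale=self.reward_cfg.reward_scale,
        )

    def _diagnose(self, state: DialogueState) -> tuple[str, list[str]]:
        ranking = predict_disease(self.classifier, encode_symptom_status(state.status))
        return ranking[0][0], [d for d, _ in ranking]

    def run_episode(
        self, record: PatientRecord, explore: bool, rng: np.random.Generator
    ) -> EpisodeLog:
        cfg, rcfg = self.agent_cfg, self.reward_cfg
        state = reset(record, self.graph, cfg.k)
        log = EpisodeLog(
            record_id=record.record_id,
            self_report=sorted(record.self_report()),
            true_disease=record.disease,
            n_implicit_true=len(record.true_implicit_symptoms()),
        )
        eps = cfg.epsilon if explore else 0.0
        activations = 0
        max_activations = 4 * rcfg.N  # backstop; fruitless masking already ensures progress
        # departments whose worker returned control without querying since the
        # state last changed: re-activating them is a no-op, so mask them until
        # a query alters the state (guarantees episode progress)
        fruitless: set[str] = set()
        while True:
            c_vec = self._encode(state)
            c_mask = np.ones(len(self.controller.action_space), dtype=bool)
            for i, name in enumerate(self.controller.action_space[:-1]):
                if name in fruitless:
                    c_mask[i] = False
            c_act = select_action(q_values(self.controller, c_vec), eps, c_mask, rng)
            c_name = self.controller.action_space[c_act]
            if c_name == self.DIAGNOSE:
                predicted, ranking = self._diagnose(state)
                log.predicted_disease = predicted
                log.disease_ranking = ranking
                log.success = predicted == record.disease
                log.terminated_by = "diagnosis"
                log.terminal_reward = internal_reward(
                    "success" if log.success else "failure", rcfg
                )
                if explore:
                    self.controller.replay.push(Transition(
                        c_vec, c_act,
                        controller_reward([log.terminal_reward], rcfg.gamma_c, terminal=True),
                        c_vec, True,
                    ))
                return log

            # departmental subtask
            group = c_name
            worker = self.departments[group]
            log.department_activations.append(group)
            activations += 1
            internal_rewards: list[float] = []
            hit_limit = False
            while True:
                w_vec = self._encode(state)
                mask = np.ones(len(worker.action_space), dtype=bool)
                if cfg.mask_known_eval and not explore:
                    for i, name in enumerate(worker.action_space[:-1]):
                        if state.status_of(name) is not None:
                            mask[i] = False
                w_act = select_action(q_values(worker, w_vec), eps, mask, rng)
                w_name = worker.action_space[w_act]
                if w_name == self.RETURN:
                    if explore:
                        worker.replay.push(Transition(w_vec, w_act, 0.0, w_vec, True))
                    break
                rec_before = state.recommended
                as_t = context_association(self.graph, w_name, state.confirmed_set)
                state, answer, repetition, hit_limit = step(
                    state, record, w_name, self.graph, cfg.k, max_turns=rcfg.N
                )
                if repetition:
                    r_d = internal_reward("repetition", rcfg)
                elif answer:
                    r_d = internal_reward("match", rcfg)
                else:
                    r_d = internal_reward("other", rcfg)
                r_rr = recommendation_reward(w_name, rec_before, rcfg)
                r_ar = association_reward(as_t, rcfg)
                r = total_reward(r_d, r_rr, r_ar, rcfg)
                state.last_reward = r
                internal_rewards.append(r_d)
                log.queries.append(QueryOutcome(w_name, answer, r_d, r_rr, r_ar))
                if explore:
                    worker.replay.push(Transition(
                        w_vec, w_act, r, self._encode(state), hit_limit
                    ))
                if hit_limit:
                    break

            if internal_rewards:
                fruitless.clear()
            else:
                fruitless.add(group)

            if hit_limit or activations >= max_activations:
                log.terminated_by = "turn_limit"
                log.success = False
                fail = internal_reward("failure", rcfg)
                log.terminal_reward = fail
                if explore:
                    rc = controller_reward(internal_rewards + [fail], rcfg.gamma_c)
                    self.controller.replay.push(Transition(
                        c_vec, c_act, rc, self._encode(state), True
                    ))
                return log

            if explore:
                rc = (controller_reward(internal_rewards, rcfg.gamma_c)
                      if internal_rewards else 0.0)
                self.controller.replay.push(Transition(
                    c_vec, c_act, rc, self._encode(state), False
                ))


class FlatPolicyAgent:
    """Single-policy baseline: one action space of all symptoms plus all diseases."""

    def __init__(
        self,
        dataset: DiagnosisDataset,
        graph: CooccurrenceGraph,
        reward_cfg: RewardConfig,
        agent_cfg: AgentConfig,
        rng: np.random.Generator,
    ):
        self.graph = graph
        self.reward_cfg = reward_cfg
        self.agent_cfg = agent_cfg
        self.symptoms = list(dataset.symptom_vocabulary)
        self.diseases = list(dataset.disease_vocabulary)
        n_in = 5 * len(graph.symptom_index) + 2
        self.policy = QPolicy(
            action_space=self.symptoms + self.diseases,
            n_inputs=n_in,
            hidden=agent_cfg.hidden,
            epsilon=agent_cfg.epsilon,
            gamma=reward_cfg.gamma_w,
            mode=agent_cfg.mode,
            replay_capacity=agent_cfg.replay_capacity,
            lr=agent_cfg.lr,
            rng=rng,
        )

    @property
    def policies(self) -> list[QPolicy]:
        return [self.policy]

    def run_episode(
        self, record: PatientRecord, explore: bool, rng: np.random.Generator
    ) -> EpisodeLog:
        cfg, rcfg = self.agent_cfg, self.reward_cfg
        state = reset(record, self.graph, cfg.k)
        log = EpisodeLog(
            record_id=record.record_id,
            self_report=sorted(record.self_report()),
            true_disease=record.disease,
            n_implicit_true=len(record.true_implicit_symptoms()),
        )
        eps = cfg.epsilon if explore else 0.0
        n_sym = len(self.symptoms)
        while True:
            vec = encode_state(state, self.graph.symptom_index,
                               max_turns=rcfg.N, reward_scale=rcfg.reward_scale)
            mask = np.ones(len(self.policy.action_space), dtype=bool)
            if cfg.mask_known_eval and not explore:
                for i, name in enumerate(self.symptoms):
                    if state.status_of(name) is not None:
                        mask[i] = False
            act = select_action(q_values(self.policy, vec), eps, mask, rng)
            if act >= n_sym:  # disease action terminates the episode
                predicted = self.policy.action_space[act]
                log.predicted_disease = predicted
                log.success = predicted == record.disease
                log.terminated_by = "diagnosis"
                log.terminal_reward = internal_reward(
                    "success" if log.success else "failure", rcfg
                )
                if explore:
                    self.policy.replay.push(Transition(
                        vec, act, log.terminal_reward, vec, True
                    ))
                return log
            name = self.symptoms[act]
            rec_before = state.recommended
            as_t = context_association(self.graph, name, state.confirmed_set)
            state, answer, repetition, hit_limit = step(
                state, record, name, self.graph, cfg.k, max_turns=rcfg.N
            )
            if repetition:
                r_d = internal_reward("repetition", rcfg)
            elif answer:
                r_d = internal_reward("match", rcfg)
            else:
                r_d = internal_reward("other", rcfg)
            r = total_reward(r_d, recommendation_reward(name, rec_before, rcfg),
                             association_reward(as_t, rcfg), rcfg)
            state.last_reward = r
            log.queries.append(QueryOutcome(
                name, answer, r_d,
                recommendation_reward(name, rec_before, rcfg),
                association_reward(as_t, rcfg),
            ))
            next_vec = encode_state(state, self.graph.symptom_index,
                                    max_turns=rcfg.N, reward_scale=rcfg.reward_scale)
            if explore:
                self.policy.replay.push(Transition(vec, act, r, next_vec, hit_limit))
            if hit_limit:
                log.terminated_by = "turn_limit"
                log.terminal_reward = internal_reward("failure", rcfg)
                return log


def run_scripted_episode(
    record: PatientRecord,
    queries: Sequence[str],
    graph: CooccurrenceGraph,
    reward_cfg: RewardConfig,
    k: int = 5,
    predicted_disease: Optional[str] = None,
    classifier: Optional[DiseaseClassifier] = None,
) -> EpisodeLog:
    """Replay a fixed query sequence against the simulator and score it.

    Useful for encoding printed case-study dialogues as fixtures and for
    scripted reference agents (e.g. always-query-top-recommendation). The final
    diagnosis comes from ``predicted_disease`` if given, else the classifier,
    else is absent.
    """
    state = reset(record, graph, k)
    log = EpisodeLog(
        record_id=record.record_id,
        self_report=sorted(record.self_report()),
        true_disease=record.disease,
        n_implicit_true=len(record.true_implicit_symptoms()),
    )
    for name in queries:
        rec_before = state.recommended
        as_t = context_association(graph, name, state.confirmed_set)
        state, answer, repetition, hit_limit = step(
            state, record, name, graph, k, max_turns=reward_cfg.N
        )
        if repetition:
            r_d = internal_reward("repetition", reward_cfg)
        elif answer:
            r_d = internal_reward("match", reward_cfg)
        else:
            r_d = internal_reward("other", reward_cfg)
        r_rr = recommendation_reward(name, rec_before, reward_cfg)
        r_ar = association_reward(as_t, reward_cfg)
        state.last_reward = total_reward(r_d, r_rr, r_ar, reward_cfg)
        log.queries.append(QueryOutcome(name, answer, r_d, r_rr, r_ar))
        if hit_limit:
            log.terminated_by = "turn_limit"
            break
    if predicted_disease is None and classifier is not None:
        ranking = predict_disease(classifier, encode_symptom_status(state.status))
        predicted_disease = ranking[0][0]
        log.disease_ranking = [d for d, _ in ranking]
    if predicted_disease is not None:
        log.predicted_disease = predicted_disease
        log.success = predicted_disease == record.disease
        log.terminal_reward = internal_reward(
            "success" if log.success else "failure", reward_cfg
        )
    return log


def train(
    agent: HierarchicalAgent | FlatPolicyAgent,
    dataset: DiagnosisDataset,
    epochs: int,
    episodes_per_epoch: int,
    seed: int,
) -> list[dict]:
    """Episode / update / sync training loop; deterministic given seed.

    Each epoch simulates ``episodes_per_epoch`` dialogues on records sampled
    uniformly from the training set, then applies ``updates_per_epoch`` batch
    updates to every policy whose replay holds at least one batch, then syncs
    target networks on the configured cadence. Returns per-epoch rows of
    success rate, average turns, average reward and mean loss.
    """
    if epochs < 0 or episodes_per_epoch <= 0:
        raise ValueError("invalid training schedule")
    if not dataset.records:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(seed)
    cfg = agent.agent_cfg
    rows: list[dict] = []
    for epoch in range(epochs):
        logs = []
        for _ in range(episodes_per_epoch):
            rec = dataset.records[rng.integers(0, len(dataset.records))]
            logs.append(agent.run_episode(rec, explore=True, rng=rng))
        losses = []
        for policy in agent.policies:
            if len(policy.replay) >= cfg.batch_size:
                for _ in range(cfg.updates_per_epoch):
                    batch = policy.replay.sample(cfg.batch_size, rng)
                    losses.append(train_step(policy, batch))
        if (epoch + 1) % cfg.sync_every == 0:
            for policy in agent.policies:
                sync_target(policy)
        rows.append({
            "epoch": epoch,
            "success_rate": float(np.mean([l.success for l in logs])),
            "avg_turns": float(np.mean([l.turns for l in logs])),
            "avg_reward": float(np.mean([l.total_reward for l in logs])),
            "loss": float(np.mean(losses)) if losses else float("nan"),
        })
    return rows


def evaluate_agent(
    agent: HierarchicalAgent | FlatPolicyAgent,
    records: Sequence[PatientRecord],
    seed: int = 0,
) -> list[EpisodeLog]:
    """Greedy (epsilon = 0) rollout over the given records."""
    rng = np.random.default_rng(seed)
    return [agent.run_episode(rec, explore=False, rng=rng) for rec in records]


def save_agent(agent: HierarchicalAgent, path: str | Path, meta: Optional[dict] = None) -> None:
    """Checkpoint the agent (network parameters, config, classifier) to disk."""
    payload = {
        "meta": meta or {},
        "reward_cfg": agent.reward_cfg,
        "agent_cfg": agent.agent_cfg,
        "groups": agent.groups,
        "dept_symptoms": agent.dept_symptoms,
        "graph_symptoms": agent.graph.symptom_index,
        "graph_counts": agent.graph.counts,
        "classifier": agent.classifier,
        "controller": agent.controller.net.get_params(),
        "workers": {g: agent.departments[g].net.get_params() for g in agent.groups},
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_agent(path: str | Path) -> HierarchicalAgent:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    graph = CooccurrenceGraph(payload["graph_symptoms"], payload["graph_counts"])
    agent = HierarchicalAgent.__new__(HierarchicalAgent)
    agent.graph = graph
    agent.classifier = payload["classifier"]
    agent.reward_cfg = payload["reward_cfg"]
    agent.agent_cfg = payload["agent_cfg"]
    agent.groups = payload["groups"]
    agent.dept_symptoms = payload["dept_symptoms"]
    cfg, rcfg = agent.agent_cfg, agent.reward_cfg
    n_in = 5 * len(graph.symptom_index) + 2
    rng = np.random.default_rng(0)
    agent.controller = QPolicy(
        agent.groups + [HierarchicalAgent.DIAGNOSE], n_in, cfg.hidden, cfg.epsilon,
        rcfg.gamma_c, cfg.mode, cfg.replay_capacity, cfg.lr, rng,
    )
    agent.controller.net.set_params(payload["controller"])
    sync_target(agent.controller)
    agent.departments = {}
    for g in agent.groups:
        pol = QPolicy(
            agent.dept_symptoms[g] + [HierarchicalAgent.RETURN], n_in, cfg.hidden,
            cfg.epsilon, rcfg.gamma_w, cfg.mode, cfg.replay_capacity, cfg.lr, rng,
        )
        pol.net.set_params(payload["workers"][g])
        sync_target(pol)
        agent.departments[g] = pol
    return agent
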