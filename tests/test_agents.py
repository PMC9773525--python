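"""Q-policies, TD targets, training mechanics and hierarchical episode execution."""

import numpy as np
import pytest

from symdiag.agents import (
    AgentConfig,
    HierarchicalAgent,
    FlatPolicyAgent,
    QPolicy,
    Transition,
    evaluate_agent,
    load_agent,
    q_values,
    run_scripted_episode,
    save_agent,
    select_action,
    sync_target,
    td_targets,
    train,
    train_step,
)
from symdiag.association import build_cooccurrence
from symdiag.classifier import train_classifier
from symdiag.rewards import RewardConfig


def make_policy(n_in=4, n_actions=3, hidden=8, gamma=0.9, mode="dqn", seed=0,
                lr=0.05):
    return QPolicy(
        action_space=[f"a{i}" for i in range(n_actions)],
        n_inputs=n_in, hidden=hidden, epsilon=0.1, gamma=gamma, mode=mode,
        replay_capacity=100, lr=lr, rng=np.random.default_rng(seed),
    )


def set_constant_output(net, values):
    """Zero the network except output biases, making it a constant function."""
    params = net.get_params()
    params["W1"][:] = 0.0
    params["b1"][:] = 0.0
    params["W2"][:] = 0.0
    params["b2"][:] = np.asarray(values, dtype=float)
    net.set_params(params)


class TestQValues:
    def test_output_length_and_determinism(self):
        policy = make_policy()
        x = np.ones(4)
        v1, v2 = q_values(policy, x), q_values(policy, x)
        assert v1.shape == (3,)
        np.testing.assert_array_equal(v1, v2)
        assert np.all(np.isfinite(v1))

    def test_zeroed_output_layer_gives_equal_values(self):
        policy = make_policy()
        set_constant_output(policy.net, [0.0, 0.0, 0.0])
        v = q_values(policy, np.random.default_rng(0).normal(size=4))
        np.testing.assert_allclose(v, 0.0)

    def test_length_mismatch_rejected(self):
        policy = make_policy()
        with pytest.raises(ValueError):
            q_values(policy, np.ones(5))


class TestSelectAction:
    def test_pure_greedy(self):
        rng = np.random.default_rng(0)
        assert select_action(np.array([1.0, 3.0, 2.0]), 0.0, None, rng) == 1

    def test_greedy_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(0)
        assert select_action(np.array([2.0, 5.0, 5.0]), 0.0, None, rng) == 1

    def test_full_exploration_uniform(self):
        rng = np.random.default_rng(42)
        values = np.array([0.0, 10.0, 0.0, 0.0])
        n = 100_000
        draws = np.array([select_action(values, 1.0, None, rng) for _ in range(n)])
        freqs = np.bincount(draws, minlength=4) / n
        # 99% CI half-width for a fair 4-sided frequency
        half = 2.576 * np.sqrt(0.25 * 0.75 / n)
        np.testing.assert_allclose(freqs, 0.25, atol=3 * half)

    def test_exploration_fraction_near_epsilon(self):
        rng = np.random.default_rng(7)
        values = np.array([0.0, 10.0, 0.0, 0.0])
        n = 50_000
        draws = np.array([select_action(values, 0.1, None, rng) for _ in range(n)])
        non_greedy = np.mean(draws != 1)
        # epsilon * (3/4) of draws land off the argmax
        assert non_greedy == pytest.approx(0.075, abs=0.01)

    def test_mask_restricts_choice(self):
        rng = np.random.default_rng(0)
        mask = np.array([False, False, True])
        assert select_action(np.array([9.0, 8.0, 1.0]), 0.0, mask, rng) == 2

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            select_action(np.zeros(3), 0.0, np.zeros(3, dtype=bool),
                          np.random.default_rng(0))


class TestTDTargets:
    def test_terminal_target_is_reward(self):
        policy = make_policy(n_actions=2)
        t = Transition(np.zeros(4), 0, 84.0, np.zeros(4), True)
        np.testing.assert_allclose(td_targets([t], policy), [84.0])

    def test_dqn_bootstrap(self):
        policy = make_policy(n_actions=2, gamma=0.9)
        set_constant_output(policy.target_net, [2.0, 5.0])
        t = Transition(np.zeros(4), 0, 1.0, np.zeros(4), False)
        np.testing.assert_allclose(td_targets([t], policy, mode="dqn"), [5.5])

    def test_ddqn_decouples_selection_from_evaluation(self):
        policy = make_policy(n_actions=2, gamma=0.9)
        set_constant_output(policy.net, [5.0, 2.0])        # behavior argmax -> 0
        set_constant_output(policy.target_net, [2.0, 5.0])  # evaluated at 0 -> 2
        t = Transition(np.zeros(4), 0, 1.0, np.zeros(4), False)
        np.testing.assert_allclose(td_targets([t], policy, mode="ddqn"), [2.8])

    def test_ddqn_never_exceeds_dqn(self):
        policy = make_policy(n_in=6, n_actions=4, seed=3)
        rng = np.random.default_rng(5)
        batch = [
            Transition(rng.normal(size=6), int(rng.integers(4)), rng.normal(),
                       rng.normal(size=6), False)
            for _ in range(64)
        ]
        dqn = td_targets(batch, policy, mode="dqn")
        ddqn = td_targets(batch, policy, mode="ddqn")
        assert np.all(ddqn <= dqn + 1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            td_targets([], make_policy())


class TestTrainStep:
    def test_fixed_point_has_zero_loss(self):
        policy = make_policy(n_actions=2)
        x = np.ones(4)
        q = q_values(policy, x)
        batch = [Transition(x, 0, float(q[0]), x, True)]
        before = policy.net.get_params()
        loss = train_step(policy, batch)
        assert loss == pytest.approx(0.0, abs=1e-20)
        after = policy.net.get_params()
        for key in before:
            np.testing.assert_allclose(before[key], after[key], atol=1e-12)

    def test_loss_decreases_on_frozen_batch(self):
        policy = make_policy(seed=1, lr=0.01)
        rng = np.random.default_rng(2)
        batch = [
            Transition(rng.normal(size=4), int(rng.integers(3)), rng.normal(),
                       rng.normal(size=4), True)
            for _ in range(16)
        ]
        losses = [train_step(policy, batch) for _ in range(50)]
        assert losses[-1] <= losses[0]
        assert all(np.isfinite(l) for l in losses)


class TestSyncTarget:
    def test_nets_identical_after_sync(self):
        policy = make_policy()
        batch = [Transition(np.ones(4), 0, 1.0, np.ones(4), True)]
        train_step(policy, batch)  # desynchronize
        sync_target(policy)
        x = np.linspace(-1, 1, 4)
        np.testing.assert_array_equal(q_values(policy, x),
                                      q_values(policy, x, target=True))

    def test_sync_is_idempotent(self):
        policy = make_policy()
        sync_target(policy)
        before = policy.target_net.get_params()
        sync_target(policy)
        for key, val in policy.target_net.get_params().items():
            np.testing.assert_array_equal(val, before[key])


@pytest.fixture(scope="module")
def tiny_setup():
    from conftest import make_separable_dataset

    ds = make_separable_dataset(records_per_disease=20, seed=3)
    graph = build_cooccurrence(ds)
    clf = train_classifier(ds, epochs=60, seed=0, hidden=32)
    return ds, graph, clf


def make_agent(tiny_setup, seed=0, **agent_kwargs):
    ds, graph, clf = tiny_setup
    kwargs = dict(hidden=32, lr=1e-3, k=3)
    kwargs.update(agent_kwargs)
    return HierarchicalAgent(ds, graph, clf, RewardConfig(), AgentConfig(**kwargs),
                             np.random.default_rng(seed))


class TestHierarchicalEpisodes:
    def test_immediate_diagnose_gives_zero_turns(self, tiny_setup):
        agent = make_agent(tiny_setup)
        set_constant_output(agent.controller.net,
                            [0.0] * len(agent.groups) + [10.0])
        ds = tiny_setup[0]
        log = agent.run_episode(ds.records[0], explore=False,
                                rng=np.random.default_rng(0))
        assert log.turns == 0
        assert log.terminated_by == "diagnosis"
        assert log.predicted_disease is not None

    def test_turn_limit_bounds_every_episode(self, tiny_setup):
        agent = make_agent(tiny_setup)
        ds = tiny_setup[0]
        rng = np.random.default_rng(1)
        for rec in ds.records[:20]:
            log = agent.run_episode(rec, explore=True, rng=rng)
            assert log.turns <= agent.reward_cfg.N

    def test_workers_stay_inside_their_department(self, tiny_setup):
        agent = make_agent(tiny_setup)
        ds = tiny_setup[0]
        rng = np.random.default_rng(2)
        for rec in ds.records[:30]:
            log = agent.run_episode(rec, explore=True, rng=rng)
            for group, sym_list in zip(log.department_activations,
                                       _activation_queries(log, agent)):
                for s in sym_list:
                    assert s in agent.dept_symptoms[group]

    def test_scripted_replay_of_published_case(self, case_dataset, case_graph):
        """The 7-turn investigation printed for case 13947 succeeds when replayed."""
        rec = case_dataset.records[0]
        queries = ["ache all over", "neck pain", "headache", "back pain",
                   "loss of sensation", "paresthesia", "leg pain"]
        log = run_scripted_episode(rec, queries, case_graph, RewardConfig(),
                                   predicted_disease="carpal tunnel syndrome")
        assert log.success is True
        assert log.turns == 7
        answers = [q.answer for q in log.queries]
        assert answers == [False, True, False, False, True, False, False]


def _activation_queries(log, agent):
    """Split the query stream by department activation via symptom membership."""
    # activations are sequential; a query belongs to the most recent activation
    out = [[] for _ in log.department_activations]
    idx = -1
    remaining = list(log.queries)
    # reconstruct greedily: each query is assigned to the first activation whose
    # department contains it, scanning activations in order
    for q in remaining:
        placed = False
        for i in range(max(idx, 0), len(out)):
            if q.symptom in agent.dept_symptoms[log.department_activations[i]]:
                out[i].append(q.symptom)
                idx = i
                placed = True
                break
        if not placed:
            out[-1].append(q.symptom)
    return out


class TestTraining:
    def test_zero_epochs_leaves_parameters_untouched(self, tiny_setup):
        agent = make_agent(tiny_setup)
        before = agent.controller.net.get_params()
        rows = train(agent, tiny_setup[0], epochs=0, episodes_per_epoch=10, seed=0)
        assert rows == []
        for key, val in agent.controller.net.get_params().items():
            np.testing.assert_array_equal(val, before[key])

    def test_training_is_deterministic_in_seed(self, tiny_setup):
        rows_a = train(make_agent(tiny_setup, seed=5), tiny_setup[0],
                       epochs=3, episodes_per_epoch=10, seed=9)
        rows_b = train(make_agent(tiny_setup, seed=5), tiny_setup[0],
                       epochs=3, episodes_per_epoch=10, seed=9)
        assert rows_a == rows_b

    def test_log_rows_carry_all_fields(self, tiny_setup):
        rows = train(make_agent(tiny_setup), tiny_setup[0], epochs=2,
                     episodes_per_epoch=5, seed=0)
        assert len(rows) == 2
        assert set(rows[0]) == {"epoch", "success_rate", "avg_turns",
                                "avg_reward", "loss"}

    def test_invalid_schedule_rejected(self, tiny_setup):
        with pytest.raises(ValueError):
            train(make_agent(tiny_setup), tiny_setup[0], epochs=1,
                  episodes_per_epoch=0, seed=0)

    def test_flat_policy_smoke(self, tiny_setup):
        ds, graph, _ = tiny_setup
        flat = FlatPolicyAgent(ds, graph, RewardConfig(),
                               AgentConfig(hidden=32, lr=1e-3, k=3),
                               np.random.default_rng(0))
        rows = train(flat, ds, epochs=2, episodes_per_epoch=5, seed=1)
        assert len(rows) == 2
        log = flat.run_episode(ds.records[0], explore=False,
                               rng=np.random.default_rng(0))
        assert log.turns <= flat.reward_cfg.N


class TestCheckpointing:
    def test_round_trip_preserves_behavior(self, tiny_setup, tmp_path):
        agent = make_agent(tiny_setup)
        train(agent, tiny_setup[0], epochs=2, episodes_per_epoch=10, seed=0)
        path = tmp_path / "ckpt.pkl"
        save_agent(agent, path)
        loaded = load_agent(path)
        eps_a = evaluate_agent(agent, tiny_setup[0].records[:10], seed=3)
        eps_b = evaluate_agent(loaded, tiny_setup[0].records[:10], seed=3)
        assert [e.predicted_disease for e in eps_a] == \
               [e.predicted_disease for e in eps_b]
        assert [e.turns for e in eps_a] == [e.turns for e in eps_b]
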