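"""Reward critics shaping the investigation policies.

Three critics score each symptom query:

* the internal critic — task progress: ``+t1*N`` on a successful diagnosis,
  ``+t2*N`` when the queried symptom is confirmed (a *match*), ``-t3*N`` for
  re-querying a known symptom, ``0`` otherwise; a failed diagnosis (wrong
  disease or turn limit) earns ``-t1*N``, mirroring the success magnitude;
* the recommendation critic — ``+t4`` if the query is among the current top-K
  recommendations, else ``-t5``;
* the association critic — banded on the query's context-association score
  ``as_t``: ``+t4`` above the desired threshold ``h``, ``+1`` in the middle
  band ``(l, h]``, ``-t5`` at or below the lower threshold ``l``.

The worker's per-turn shaped reward is their sum; the controller's reward for a
department activation is the discounted sum of the subtask's internal rewards,
and the raw terminal reward for the diagnose action.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .association import Recommendation

__all__ = [
    "RewardConfig",
    "internal_reward",
    "recommendation_reward",
    "association_reward",
    "total_reward",
    "controller_reward",
]

_EVENTS = frozenset({"success", "failure", "match", "repetition", "other"})


@dataclass(frozen=True)
class RewardConfig:
    """Shaping scalars, thresholds and discounts.

    Defaults follow the benchmark setup: t1..t5 = 3, 2, 2, 15, 2, turn limit
    N = 28, controller discount 0.9, worker discount 0.95. The association
    thresholds l and h are tuned so the middle band is reachable at typical
    association magnitudes. ``use_recommendation``/``use_association`` are the
    ablation switches (both off reduces the shaped reward to the internal
    critic alone).
    """

    t1: float = 3.0
    t2: float = 2.0
    t3: float = 2.0
    t4: float = 15.0
    t5: float = 2.0
    N: int = 28
    l: float = 0.05
    h: float = 0.20
    gamma_c: float = 0.9
    gamma_w: float = 0.95
    use_recommendation: bool = True
    use_association: bool = True

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.l < self.h:
            raise ValueError("thresholds must satisfy 0 <= l < h")
        for name in ("gamma_c", "gamma_w"):
            g = getattr(self, name)
            if not 0.0 < g <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")

    @property
    def reward_scale(self) -> float:
        """Maximum attainable per-turn reward magnitude; used to bound state features."""
        return max(self.t1, self.t2, self.t3) * self.N + 2.0 * self.t4


def internal_reward(event: str, cfg: RewardConfig) -> float:
    """Internal critic: event in {success, failure, match, repetition, other}."""
    if event not in _EVENTS:
        raise ValueError(f"unknown reward event {event!r}")
    if event == "success":
        return cfg.t1 * cfg.N
    if event == "failure":
        return -cfg.t1 * cfg.N
    if event == "match":
        return cfg.t2 * cfg.N
    if event == "repetition":
        return -cfg.t3 * cfg.N
    return 0.0


def recommendation_reward(
    queried: str, recommended: Optional[Recommendation], cfg: RewardConfig
) -> float:
    """+t4 if the query is currently recommended, else -t5 (empty RS always penalizes)."""
    if recommended is not None and queried in recommended:
        return cfg.t4
    return -cfg.t5


def association_reward(as_t: float, cfg: RewardConfig) -> float:
    """Banded reward on the context-association score of the query.

    Strictly above h: +t4. Middle band (l, h] (boundary h assigned to the
    middle band): +1. At or below l: -t5.
    """
    if as_t > cfg.h:
        return cfg.t4
    if cfg.l < as_t <= cfg.h:
        return 1.0
    return -cfg.t5


def total_reward(
    r_d: float, r_rr: float, r_ar: float, cfg: Optional[RewardConfig] = None
) -> float:
    """Worker's shaped per-turn reward r = r_d + (r_rr + r_ar).

    The config's ablation flags zero the recommendation and/or association
    components (no-ARM reduces to the internal critic exactly).
    """
    if cfg is not None:
        if not cfg.use_recommendation:
            r_rr = 0.0
        if not cfg.use_association:
            r_ar = 0.0
    return r_d + r_rr + r_ar


def controller_reward(
    worker_rewards: Sequence[float], gamma_c: float, terminal: bool = False
) -> float:
    """Controller reward for one activation.

    For a department activation: the discounted sum ``sum_i gamma_c^i * r_i``
    over the subtask's per-turn internal rewards (i starting at 1). For the
    diagnose action (``terminal=True``): the raw terminal reward, which must be
    a singleton.
    """
    if not worker_rewards:
        raise ValueError("worker_rewards must be nonempty")
    if terminal:
        if len(worker_rewards) != 1:
            raise ValueError("diagnose action carries a single terminal reward")
        return float(worker_rewards[0])
    return float(sum(gamma_c ** (i + 1) * r for i, r in enumerate(worker_rewards)))
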