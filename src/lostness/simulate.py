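"""Synthetic worlds, playthroughs, and cohorts.

The study data this package analyses — navigation logs of players
completing gathering tasks in a node-based game, plus a post-game
knowledge test and experience questionnaires — is emulated here so the
whole pipeline can be exercised and validated end to end.

Three generators, all driven by one explicit seed:

* :func:`generate_world` — a connected backbone of location nodes (rooms
  with a few extra corridors), with door-like *interactable* nodes and
  *object* item nodes attached as leaves.  Each task starts at a door
  whose keyword is the task's first objective; the remaining objectives
  target item nodes elsewhere.
* :func:`simulate_playthrough` — an ε-greedy walker: with probability
  1−ε it takes the next hop of the (lexicographically deterministic)
  shortest path toward its current goal, otherwise a uniformly random
  neighbour.  ε = 0 is a perfect navigator, ε = 1 a pure random walk, so
  the single parameter spans efficient to fully disoriented play.
* :func:`simulate_cohort` — a table of players with measured lostness
  values, experience scales, and a knowledge score whose latent
  propensity carries *planted standardized effects* (defaults from the
  study this emulates: local lostness −0.667, presence −0.399, cognitive
  interest 0.346).  Planted betas are the true standardized coefficients
  of the latent propensity; its residual variance is whatever brings the
  latent variance to one, which is only feasible while the implied
  multiple correlation stays at or below one.  Item responses are then
  drawn from a two-parameter probit (normal-ogive) item model, so the
  observed proportion-correct score is an attenuated measurement of the
  latent propensity, as a real test score is.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, UnreachableError
from .events import EventKind, EventLog, NavigationEvent
from .metrics import player_report
from .world import (
    Node,
    NodeKind,
    Objective,
    SpatialGraph,
    Task,
    TaskSet,
    optimal_visit_order,
)

__all__ = [
    "AgentConfig",
    "KnowledgeTestSpec",
    "KnowledgeItem",
    "CohortSpec",
    "CohortRecord",
    "generate_world",
    "simulate_playthrough",
    "generate_knowledge_test",
    "simulate_cohort",
]

_EPOCH = datetime(2020, 1, 1, 0, 0, 0)


@dataclass(frozen=True)
class AgentConfig:
    """Walk policy of a simulated player.

    Three independent behavioral axes, all zero for a perfect navigator:

    * ``wander_prob`` (ε) — per step, probability of a uniformly random
      neighbour instead of the next shortest-path hop.
    * ``order_noise`` — per task, probability of attacking the objectives
      in a random order instead of the minimum route's order.  A bad
      order inflates the task window against its fixed minimum route but
      barely touches the objective segments, whose R adapts to the order
      actually taken.
    * ``explore_rate`` — mean number of free-roam steps taken before
      heading to each task (curiosity between tasks, Poisson-drawn).
      These fall outside every task window, so they load only the local
      measure.
    """

    wander_prob: float = 0.0
    order_noise: float = 0.0
    explore_rate: float = 0.0
    max_steps: int = 5000
    seed: int = 0
    player: str = "agent"

    def __post_init__(self) -> None:
        if not 0.0 <= self.wander_prob <= 1.0:
            raise ConfigurationError("wander_prob must lie in [0, 1]")
        if not 0.0 <= self.order_noise <= 1.0:
            raise ConfigurationError("order_noise must lie in [0, 1]")
        if self.explore_rate < 0.0:
            raise ConfigurationError("explore_rate must be nonnegative")
        if self.max_steps < 1:
            raise ConfigurationError("max_steps must be positive")


@dataclass(frozen=True)
class KnowledgeTestSpec:
    """Composition of the post-game true/false knowledge test: 24 items,
    8 of them spatial, half keyed true (the study's instrument)."""

    n_items: int = 24
    n_spatial: int = 8
    true_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ConfigurationError("n_items must be positive")
        if not 0 <= self.n_spatial <= self.n_items:
            raise ConfigurationError("n_spatial must lie in [0, n_items]")
        if not 0.0 <= self.true_fraction <= 1.0:
            raise ConfigurationError("true_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class KnowledgeItem:
    id: str
    keyed_true: bool
    spatial: bool


def generate_knowledge_test(
    spec: KnowledgeTestSpec = KnowledgeTestSpec(), seed: int = 0
) -> list[KnowledgeItem]:
    """Build a randomized answer key with the configured composition."""
    rng = np.random.default_rng(seed)
    n = spec.n_items
    n_true = round(spec.true_fraction * n)
    keyed = np.zeros(n, dtype=bool)
    keyed[rng.choice(n, size=n_true, replace=False)] = True
    spatial = np.zeros(n, dtype=bool)
    spatial[rng.choice(n, size=spec.n_spatial, replace=False)] = True
    width = len(str(n - 1))
    return [
        KnowledgeItem(id=f"q{i:0{width}d}", keyed_true=bool(keyed[i]), spatial=bool(spatial[i]))
        for i in range(n)
    ]


# ---------------------------------------------------------------------
# world generation


def generate_world(
    n_locations: int = 12,
    n_tasks: int = 4,
    objectives_per_task: int = 3,
    seed: int = 0,
    extra_edge_fraction: float = 0.35,
) -> tuple[SpatialGraph, TaskSet]:
    """A connected game world with tasks, deterministic under ``seed``.

    Locations form a random tree plus ``extra_edge_fraction * n_locations``
    shortcut edges (so detours are possible); every door and item is a
    leaf on a random location.  Objective targets are distinct nodes.
    """
    if n_locations < 2:
        raise ConfigurationError("need at least 2 locations")
    if n_tasks < 1 or objectives_per_task < 1:
        raise ConfigurationError("need at least one task with one objective")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_locations - 1)))
    locations = [f"loc{i:0{width}d}" for i in range(n_locations)]
    nodes = [Node(loc, NodeKind.LOCATION, label=f"room {i}") for i, loc in enumerate(locations)]
    edges: set[tuple[str, str]] = set()
    for i in range(1, n_locations):
        j = int(rng.integers(0, i))
        edges.add((locations[j], locations[i]))
    n_extra = int(round(extra_edge_fraction * n_locations))
    attempts = 0
    while n_extra > 0 and attempts < 50 * n_locations:
        a, b = rng.choice(n_locations, size=2, replace=False)
        key = (locations[min(a, b)], locations[max(a, b)])
        attempts += 1
        if key not in edges:
            edges.add(key)
            n_extra -= 1

    tasks = []
    for t in range(n_tasks):
        door = f"door{t}"
        door_loc = locations[int(rng.integers(0, n_locations))]
        nodes.append(Node(door, NodeKind.INTERACTABLE, label=f"door of task {t}"))
        edges.add((door_loc, door))
        objectives = [Objective(f"obj{t}_0", target_node=door, label="task keyword")]
        for k in range(1, objectives_per_task):
            item = f"item{t}_{k}"
            item_loc = locations[int(rng.integers(0, n_locations))]
            nodes.append(Node(item, NodeKind.OBJECT, label=f"item {k} of task {t}"))
            edges.add((item_loc, item))
            objectives.append(Objective(f"obj{t}_{k}", target_node=item))
        tasks.append(Task(id=f"task{t}", start_node=door, objectives=tuple(objectives)))

    graph = SpatialGraph(nodes, sorted(edges), game_start_node=locations[0])
    task_set = TaskSet(tasks=tuple(tasks), game_start_node=locations[0])
    task_set.validate_against(graph)
    if not graph.is_connected():  # unreachable by construction; belt and braces
        raise ConfigurationError("generated world is not connected")
    return graph, task_set


# ---------------------------------------------------------------------
# playthrough simulation


def simulate_playthrough(
    graph: SpatialGraph, tasks: TaskSet, agent: AgentConfig
) -> EventLog:
    """Walk the tasks in order with an ε-greedy agent and emit the log.

    The agent activates a task by reaching its start node (task_start,
    and any objective anchored there completes on arrival), then visits
    the remaining targets in the optimal-route order.  Every node entry
    is a move (or a pickup when entering an object node); one event per
    second keeps (ts, seq) strictly increasing.  Hitting ``max_steps``
    truncates the log, which is flagged.
    """
    if tasks.game_start_node not in graph:
        raise ConfigurationError("game start node missing from graph")
    rng = np.random.default_rng(agent.seed)
    events: list[NavigationEvent] = []
    current = tasks.game_start_node
    steps = 0
    truncated = False

    def emit(kind: EventKind, node=None, task=None, objective=None) -> None:
        events.append(
            NavigationEvent(
                ts=_EPOCH + timedelta(seconds=len(events)),
                seq=len(events),
                player=agent.player,
                kind=kind,
                node=node,
                task=task,
                objective=objective,
            )
        )

    def walk_to(target: str) -> bool:
        """ε-greedy walk; returns False when the step budget ran out."""
        nonlocal current, steps
        table = graph.next_hop_table(target)
        while current != target:
            if steps >= agent.max_steps:
                return False
            if agent.wander_prob > 0 and rng.random() < agent.wander_prob:
                nbrs = graph.neighbors(current)
                nxt = nbrs[int(rng.integers(0, len(nbrs)))]
            else:
                nxt = table.get(current)
                if nxt is None:
                    raise UnreachableError(
                        f"agent at {current!r} cannot reach {target!r}"
                    )
            kind = (
                EventKind.PICKUP
                if graph.kind_of(nxt) is NodeKind.OBJECT
                else EventKind.MOVE
            )
            emit(kind, node=nxt)
            current = nxt
            steps += 1
        return True

    def roam(n_steps: int) -> bool:
        nonlocal current, steps
        for _ in range(n_steps):
            if steps >= agent.max_steps:
                return False
            nbrs = graph.neighbors(current)
            nxt = nbrs[int(rng.integers(0, len(nbrs)))]
            kind = (
                EventKind.PICKUP
                if graph.kind_of(nxt) is NodeKind.OBJECT
                else EventKind.MOVE
            )
            emit(kind, node=nxt)
            current = nxt
            steps += 1
        return True

    done = True
    for task in tasks.tasks:
        if agent.explore_rate > 0 and not roam(int(rng.poisson(agent.explore_rate))):
            done = False
            break
        if not walk_to(task.start_node):
            done = False
            break
        emit(EventKind.TASK_START, node=current, task=task.id)
        by_target: dict[str, list[Objective]] = {}
        for obj in task.objectives:
            by_target.setdefault(obj.target_node, []).append(obj)
        for obj in by_target.get(current, ()):  # anchored at the door
            emit(EventKind.OBJECTIVE_COMPLETE, node=current, objective=obj.id)
        _, order = optimal_visit_order(graph, task.start_node, task.target_nodes)
        if agent.order_noise > 0 and order and rng.random() < agent.order_noise:
            order = tuple(np.array(order)[rng.permutation(len(order))])
        for target in order:
            if not walk_to(target):
                done = False
                break
            for obj in by_target.get(current, ()):
                emit(EventKind.OBJECTIVE_COMPLETE, node=current, objective=obj.id)
        if not done:
            break
        emit(EventKind.TASK_COMPLETE, node=current, task=task.id)
    truncated = not done
    return EventLog(player=agent.player, events=tuple(events), truncated=truncated)


# ---------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class CohortSpec:
    """Study-scale cohort with a planted lostness→knowledge dependence.

    Defaults are the emulated study's conditions: ε individual
    differences uniform on [0, 0.6]; experience scales truncated-normal
    on [1, 5] around the combined-sample means; planted standardized
    effects from the combined-sample regression; a 24-item knowledge
    instrument with expected accuracy 0.576.  ``target_multiple_r``
    records that study's observed multiple correlation and bounds the
    feasible planted structure (it is not enforced as an output; see the
    methods note).
    """

    n_players: int = 24
    eps_low: float = 0.0
    eps_high: float = 0.6
    order_noise_low: float = 0.0
    order_noise_high: float = 1.0
    explore_low: float = 0.0
    explore_high: float = 10.0
    beta_local: float = -0.667
    beta_presence: float = -0.399
    beta_interest: float = 0.346
    beta_global: float = 0.0
    beta_engagement: float = 0.0
    target_multiple_r: float = 0.752
    presence_mean: float = 3.179
    presence_sd: float = 0.450
    engagement_mean: float = 2.976
    engagement_sd: float = 0.563
    interest_mean: float = 3.667
    interest_sd: float = 0.693
    mean_accuracy: float = 0.576
    item_discrimination: float = 1.0
    item_difficulty_spread: float = 0.8
    knowledge: KnowledgeTestSpec = field(default_factory=KnowledgeTestSpec)
    max_steps: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_players < 1:
            raise ConfigurationError("n_players must be positive")
        if not 0.0 <= self.eps_low <= self.eps_high <= 1.0:
            raise ConfigurationError("need 0 <= eps_low <= eps_high <= 1")
        if not 0.0 <= self.order_noise_low <= self.order_noise_high <= 1.0:
            raise ConfigurationError("need 0 <= order_noise range <= 1")
        if not 0.0 <= self.explore_low <= self.explore_high:
            raise ConfigurationError("need 0 <= explore_low <= explore_high")
        if not 0.0 < self.target_multiple_r <= 1.0:
            raise ConfigurationError("target_multiple_r must lie in (0, 1]")
        betas = np.array(self.betas)
        # conservative feasibility screen before any simulation: even a
        # perfectly collinear pair of lostness predictors must leave the
        # latent propensity a nonnegative residual variance
        implied = float(betas @ betas) + 2.0 * abs(self.beta_global * self.beta_local)
        if implied > 1.0 + 1e-9:
            raise ConfigurationError(
                f"planted effects imply multiple R^2 {implied:.3f} > 1; "
                "shrink the standardized betas"
            )
        if not 0.0 < self.mean_accuracy < 1.0:
            raise ConfigurationError("mean_accuracy must lie in (0, 1)")

    @property
    def betas(self) -> tuple[float, float, float, float, float]:
        """Order: global, local, presence, cognitive interest, engagement."""
        return (
            self.beta_global,
            self.beta_local,
            self.beta_presence,
            self.beta_interest,
            self.beta_engagement,
        )


@dataclass(frozen=True)
class CohortRecord:
    """One row of the validation analyses."""

    player: str
    epsilon: float
    global_lostness: float
    local_lostness: float
    knowledge_overall: float
    knowledge_spatial: float
    knowledge_latent: float
    presence: float
    engagement: float
    cognitive_interest: float
    complete: bool


#: column order of the cohort table
COHORT_COLUMNS = [f.name for f in CohortRecord.__dataclass_fields__.values()]  # type: ignore[attr-defined]


def _truncnorm(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _item_intercept(spec: CohortSpec, quantiles: np.ndarray) -> float:
    """Solve the item-model intercept so the expected proportion correct
    over the latent population equals ``mean_accuracy``."""
    lam = spec.item_discrimination
    s = spec.item_difficulty_spread
    scale = math.sqrt(1.0 + lam * lam)

    def gap(a0: float) -> float:
        return float(stats.norm.cdf((a0 + s * quantiles) / scale).mean()) - spec.mean_accuracy

    return float(optimize.brentq(gap, -8.0, 8.0))


def simulate_cohort(
    spec: CohortSpec = CohortSpec(),
    world: Optional[tuple[SpatialGraph, TaskSet]] = None,
    seed: Optional[int] = None,
    keep_logs: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[EventLog]]:
    """Simulate a cohort and return its table, reproducible under ``seed``.

    Per player: draw ε, play the game, measure both lostness values
    through the real segmentation pipeline, draw the experience scales,
    build the latent knowledge propensity from the planted standardized
    effects, and score the probit item model.  Players whose log ended
    before any task or objective completed are kept, flagged
    ``complete=False``, and excluded from the planting step (their
    knowledge columns are NaN).
    """
    master = np.random.default_rng(spec.seed if seed is None else seed)
    if world is None:
        world = generate_world(seed=int(master.integers(2**31)))
    graph, tasks = world

    n = spec.n_players
    eps = master.uniform(spec.eps_low, spec.eps_high, size=n)
    order_noise = master.uniform(spec.order_noise_low, spec.order_noise_high, size=n)
    explore = master.uniform(spec.explore_low, spec.explore_high, size=n)
    width = max(3, len(str(n - 1)))
    g_vals = np.empty(n)
    l_vals = np.empty(n)
    complete = np.empty(n, dtype=bool)
    players = [f"p{i:0{width}d}" for i in range(n)]
    logs: list[EventLog] = []
    for i in range(n):
        agent = AgentConfig(
            wander_prob=float(eps[i]),
            order_noise=float(order_noise[i]),
            explore_rate=float(explore[i]),
            max_steps=spec.max_steps,
            seed=int(master.integers(2**31)),
            player=players[i],
        )
        log = simulate_playthrough(graph, tasks, agent)
        if keep_logs:
            logs.append(log)
        report = player_report(log, graph, tasks)
        g_vals[i] = report.global_value
        l_vals[i] = report.local_value
        complete[i] = report.complete

    presence = _truncnorm(master, spec.presence_mean, spec.presence_sd, 1, 5, n)
    engagement = _truncnorm(master, spec.engagement_mean, spec.engagement_sd, 1, 5, n)
    interest = _truncnorm(master, spec.interest_mean, spec.interest_sd, 1, 5, n)

    ok = complete & np.isfinite(g_vals) & np.isfinite(l_vals)
    ability = np.full(n, np.nan)
    if ok.sum() >= 3:
        z_cols = np.column_stack(
            [
                _zscore(g_vals[ok]),
                _zscore(l_vals[ok]),
                _zscore(presence[ok]),
                _zscore(interest[ok]),
                _zscore(engagement[ok]),
            ]
        )
        combo = z_cols @ np.array(spec.betas)
        explained = float(combo.var(ddof=1)) if ok.sum() > 1 else 0.0
        # sample correlations can push the explained variance a little past
        # one in small cohorts; the configured effects were screened in
        # CohortSpec, so clamp rather than fail the replicate
        noise_sd = math.sqrt(max(0.0, 1.0 - explained))
        ability[ok] = combo + noise_sd * master.standard_normal(int(ok.sum()))
    elif ok.any():
        ability[ok] = master.standard_normal(int(ok.sum()))

    items = generate_knowledge_test(spec.knowledge, seed=int(master.integers(2**31)))
    n_items = spec.knowledge.n_items
    quantiles = stats.norm.ppf((np.arange(n_items) + 0.5) / n_items)
    a0 = _item_intercept(spec, quantiles)
    spatial_mask = np.array([it.spatial for it in items])
    know_overall = np.full(n, np.nan)
    know_spatial = np.full(n, np.nan)
    if ok.any():
        logits = (
            a0
            + spec.item_difficulty_spread * quantiles[None, :]
            + spec.item_discrimination * ability[ok, None]
        )
        prob = stats.norm.cdf(logits)
        correct = master.random(prob.shape) < prob
        know_overall[ok] = correct.mean(axis=1)
        if spatial_mask.any():
            know_spatial[ok] = correct[:, spatial_mask].mean(axis=1)

    records = [
        CohortRecord(
            player=players[i],
            epsilon=float(eps[i]),
            global_lostness=float(g_vals[i]),
            local_lostness=float(l_vals[i]),
            knowledge_overall=float(know_overall[i]),
            knowledge_spatial=float(know_spatial[i]),
            knowledge_latent=float(ability[i]),
            presence=float(presence[i]),
            engagement=float(engagement[i]),
            cognitive_interest=float(interest[i]),
            complete=bool(complete[i]),
        )
        for i in range(n)
    ]
    table = pd.DataFrame([r.__dict__ for r in records], columns=COHORT_COLUMNS)
    return (table, logs) if keep_logs else table
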