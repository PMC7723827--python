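"""Spatial world model: node graph, tasks/objectives, and minimum routes.

Players of node-based games move between discrete linked positions, so the
world is purely topological: a graph of *location* nodes (rooms), with
*interactable* nodes (doors, shutters) and *object* nodes (items) hanging
off them.  Tasks start at a node and bundle objectives, each bound to one
target node.  The minimum number of node entries needed to satisfy a task
or objective — the ``R`` of the lostness statistic — is computed here by
breadth-first search, with an exact search over visiting orders when a
task has several targets.

Movement is undirected unless an edge is explicitly flagged one-way.
Hop counts follow one convention throughout the package: a path counts
node *entries*, excluding the node the segment starts on, so a move to an
adjacent node costs 1 and staying put costs 0.
"""

from __future__ import annotations

import itertools
import json
import warnings
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
from pydantic import BaseModel, Field, ValidationError

from .errors import (
    ConfigurationError,
    SchemaError,
    UnknownIdentifierError,
    UnreachableError,
)

__all__ = [
    "NodeKind",
    "Node",
    "SpatialGraph",
    "Objective",
    "Task",
    "TaskSet",
    "shortest_hops",
    "min_task_route",
    "optimal_visit_order",
    "load_graph",
    "save_graph",
    "load_tasks",
    "save_tasks",
    "GRAPH_FILE_SCHEMA",
    "TASK_FILE_SCHEMA",
]

#: Beyond this many targets the exact permutation search for a task route
#: is replaced by a nearest-neighbour heuristic (with a warning).
EXACT_ROUTE_LIMIT = 8


class NodeKind(str, Enum):
    LOCATION = "location"
    INTERACTABLE = "interactable"
    OBJECT = "object"


@dataclass(frozen=True)
class Node:
    """One visitable position: a room, a door-like fixture, or an item."""

    id: str
    kind: NodeKind = NodeKind.LOCATION
    label: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("node id must be a nonempty string")


class SpatialGraph:
    """The node-link world model.

    Wraps a :class:`networkx.DiGraph`; undirected links are stored as a
    pair of arcs.  Neighbour iteration is in lexicographic node-id order
    so every traversal in the package is deterministic.
    """

    def __init__(
        self,
        nodes: Iterable[Node],
        edges: Iterable[tuple[str, str]] = (),
        directed_edges: Iterable[tuple[str, str]] = (),
        game_start_node: Optional[str] = None,
    ):
        self._nodes: dict[str, Node] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise SchemaError(f"duplicate node id {node.id!r}")
            self._nodes[node.id] = node
        self._g = nx.DiGraph()
        self._g.add_nodes_from(self._nodes)
        for a, b in edges:
            self._check_edge(a, b)
            self._g.add_edge(a, b)
            self._g.add_edge(b, a)
        for a, b in directed_edges:
            self._check_edge(a, b)
            self._g.add_edge(a, b)
        if game_start_node is not None and game_start_node not in self._nodes:
            raise SchemaError(f"game_start_node {game_start_node!r} is not a node")
        self.game_start_node = game_start_node
        # lazy per-source BFS caches; safe because the graph is immutable
        # from the outside once constructed
        self._dist_cache: dict[str, dict[str, int]] = {}
        self._next_hop_cache: dict[str, dict[str, str]] = {}

    def _check_edge(self, a: str, b: str) -> None:
        for end in (a, b):
            if end not in self._nodes:
                raise SchemaError(f"edge endpoint {end!r} is not a declared node")
        if a == b:
            raise SchemaError(f"self-loop edge on {a!r} is not allowed")

    # -- basic queries -------------------------------------------------

    @property
    def nodes(self) -> Mapping[str, Node]:
        return self._nodes

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def kind_of(self, node_id: str) -> NodeKind:
        return self._require(node_id).kind

    def _require(self, node_id: str) -> Node:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise UnknownIdentifierError(f"unknown node id {node_id!r}") from None

    def has_link(self, a: str, b: str) -> bool:
        """True when a single move from ``a`` to ``b`` is legal."""
        return self._g.has_edge(a, b)

    def neighbors(self, node_id: str) -> list[str]:
        self._require(node_id)
        return sorted(self._g.successors(node_id))

    def edge_list(self) -> list[tuple[str, str]]:
        """Canonical undirected edge list (one-way arcs appear once)."""
        seen = set()
        out = []
        for a, b in self._g.edges:
            key = (min(a, b), max(a, b))
            if self._g.has_edge(b, a):
                if key in seen:
                    continue
                seen.add(key)
                out.append(key)
            else:
                out.append((a, b))
        return sorted(out)

    def is_connected(self) -> bool:
        if len(self._nodes) <= 1:
            return True
        return nx.is_strongly_connected(self._g)

    # -- shortest paths ------------------------------------------------

    def distances_from(self, source: str) -> dict[str, int]:
        """BFS hop counts from ``source`` to every reachable node."""
        self._require(source)
        cached = self._dist_cache.get(source)
        if cached is None:
            cached = dict(nx.single_source_shortest_path_length(self._g, source))
            self._dist_cache[source] = cached
        return cached

    def next_hop_table(self, target: str) -> dict[str, str]:
        """For every node that can reach ``target``, the first step of the
        lexicographically-least shortest path toward it.

        Built by BFS from ``target`` over reversed arcs; among equidistant
        choices the smallest node id wins, so replaying the table yields
        one deterministic shortest path.
        """
        self._require(target)
        cached = self._next_hop_cache.get(target)
        if cached is not None:
            return cached
        dist: dict[str, int] = {target: 0}
        order = deque([target])
        while order:
            u = order.popleft()
            for v in sorted(self._g.predecessors(u)):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    order.append(v)
        table: dict[str, str] = {}
        for u, d in dist.items():
            if u == target:
                continue
            table[u] = min(
                v for v in self._g.successors(u) if dist.get(v, -1) == d - 1
            )
        self._next_hop_cache[target] = table
        return table


@dataclass(frozen=True)
class Objective:
    """A fact-finding goal: one specific thing found at one target node."""

    id: str
    target_node: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("objective id must be a nonempty string")


@dataclass(frozen=True)
class Task:
    """A gathering activity: from a start node, satisfy every objective.

    ``objective_count`` (the x_t weight of the global measure) is the
    number of objectives; the listed order is presentation order only.
    """

    id: str
    start_node: str
    objectives: tuple[Objective, ...]
    manual_r: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("task id must be a nonempty string")
        if not self.objectives:
            raise SchemaError(f"task {self.id!r} has no objectives")
        if self.manual_r is not None and self.manual_r < 1:
            raise SchemaError(f"task {self.id!r}: manual_r must be positive")

    @property
    def objective_count(self) -> int:
        return len(self.objectives)

    @property
    def target_nodes(self) -> tuple[str, ...]:
        return tuple(o.target_node for o in self.objectives)


@dataclass(frozen=True)
class TaskSet:
    tasks: tuple[Task, ...]
    game_start_node: str
    # kept for symmetry with the file format; per-task manual_r wins
    manual_r: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        task_ids = [t.id for t in self.tasks]
        if len(set(task_ids)) != len(task_ids):
            raise SchemaError("task ids must be unique")
        objective_ids = [o.id for t in self.tasks for o in t.objectives]
        if len(set(objective_ids)) != len(objective_ids):
            raise SchemaError("objective ids must be unique across the task set")

    def validate_against(self, graph: SpatialGraph) -> None:
        if self.game_start_node not in graph:
            raise UnknownIdentifierError(
                f"game_start_node {self.game_start_node!r} is not in the graph"
            )
        for task in self.tasks:
            if task.start_node not in graph:
                raise UnknownIdentifierError(
                    f"task {task.id!r}: start node {task.start_node!r} not in graph"
                )
            for obj in task.objectives:
                if obj.target_node not in graph:
                    raise UnknownIdentifierError(
                        f"objective {obj.id!r}: target {obj.target_node!r} not in graph"
                    )

    @property
    def task_ids(self) -> tuple[str, ...]:
        return tuple(t.id for t in self.tasks)

    def task(self, task_id: str) -> Task:
        for t in self.tasks:
            if t.id == task_id:
                return t
        raise UnknownIdentifierError(f"unknown task id {task_id!r}")

    def objective(self, objective_id: str) -> tuple[Task, Objective]:
        for t in self.tasks:
            for o in t.objectives:
                if o.id == objective_id:
                    return t, o
        raise UnknownIdentifierError(f"unknown objective id {objective_id!r}")

    def manual_r_for(self, task: Task) -> Optional[int]:
        if task.manual_r is not None:
            return task.manual_r
        return self.manual_r.get(task.id)


# ---------------------------------------------------------------------
# route computation


def shortest_hops(graph: SpatialGraph, a: str, b: str) -> int:
    """Number of edges on a minimum-length path from ``a`` to ``b``.

    Returns 0 when the endpoints coincide; raises
    :class:`UnreachableError` when no path exists.
    """
    graph._require(a)
    graph._require(b)
    dist = graph.distances_from(a).get(b)
    if dist is None:
        raise UnreachableError(f"no path from {a!r} to {b!r}")
    return dist


def optimal_visit_order(
    graph: SpatialGraph, start: str, targets: Iterable[str]
) -> tuple[int, tuple[str, ...]]:
    """Minimum total hops of a route from ``start`` visiting every target,
    plus the visiting order that achieves it.

    Exact (all permutations) for up to :data:`EXACT_ROUTE_LIMIT` distinct
    targets; nearest-neighbour with a warning beyond that.  Ties between
    orders are broken lexicographically, so the result is deterministic.
    """
    graph._require(start)
    remaining = sorted(set(targets))
    if not remaining:
        raise ConfigurationError("targets must be nonempty")
    for t in remaining:
        graph._require(t)
    # a target equal to the start is satisfied on arrival, at zero cost
    remaining = [t for t in remaining if t != start]
    if not remaining:
        return 0, ()

    def dist(a: str, b: str) -> int:
        d = graph.distances_from(a).get(b)
        if d is None:
            raise UnreachableError(f"no path from {a!r} to {b!r}")
        return d

    if len(remaining) <= EXACT_ROUTE_LIMIT:
        best: tuple[int, tuple[str, ...]] | None = None
        for perm in itertools.permutations(remaining):
            total = 0
            here = start
            for t in perm:
                total += dist(here, t)
                if best is not None and total >= best[0]:
                    # cannot beat the incumbent; lexicographic tie-break
                    # keeps the first (smallest) permutation found
                    break
                here = t
            else:
                if best is None or total < best[0]:
                    best = (total, perm)
        assert best is not None
        return best
    warnings.warn(
        f"{len(remaining)} targets exceed the exact search limit "
        f"({EXACT_ROUTE_LIMIT}); using nearest-neighbour heuristic",
        stacklevel=2,
    )
    order: list[str] = []
    total = 0
    here = start
    while remaining:
        nxt = min(remaining, key=lambda t: (dist(here, t), t))
        total += dist(here, nxt)
        order.append(nxt)
        remaining.remove(nxt)
        here = nxt
    return total, tuple(order)


def route_entry_counts(
    graph: SpatialGraph, start: str, targets: Iterable[str]
) -> tuple[int, int, tuple[str, ...]]:
    """Walk the deterministic optimal route and count its entries.

    Returns (total entries, distinct entries, visiting order).  The route
    visits targets in the order :func:`optimal_visit_order` picks and
    follows the lexicographically-least shortest path on each leg.  The
    *distinct* count is the task-level R used when scoring task windows:
    a route that must backtrack out of dead-end item nodes re-enters
    connector nodes, so its total entry count can exceed what any walker
    can show as unique entries, while its distinct count cannot (the
    walker's own path is itself a candidate route).
    """
    total, order = optimal_visit_order(graph, start, targets)
    entered: set[str] = set()
    here = start
    walked = 0
    for target in order:
        table = graph.next_hop_table(target)
        while here != target:
            here = table[here]
            entered.add(here)
            walked += 1
    assert walked == total
    return total, len(entered), order


def min_task_route(
    graph: SpatialGraph,
    start: str,
    targets: Iterable[str],
    manual_override: Optional[int] = None,
) -> int:
    """The task-level ``R``: fewest node entries of any route from
    ``start`` that reaches every target.

    A ``manual_override`` (the analyst's value from a perfect playthrough)
    is returned as-is, with a warning if it undercuts the obvious lower
    bound max_t d(start, t).
    """
    targets = sorted(set(targets))
    if not targets:
        raise ConfigurationError("targets must be nonempty")
    if manual_override is not None:
        if manual_override < 1:
            raise ConfigurationError("manual_override must be a positive integer")
        # cheap lower bound: the farthest target, and one entry per
        # distinct target away from the start
        bound = max(
            max(shortest_hops(graph, start, t) for t in targets),
            sum(1 for t in targets if t != start),
        )
        if manual_override < bound:
            warnings.warn(
                f"manual R={manual_override} is below the single-target lower "
                f"bound {bound}; accepted as configured",
                stacklevel=2,
            )
        return manual_override
    total, _ = optimal_visit_order(graph, start, targets)
    return total


# ---------------------------------------------------------------------
# file formats (JSON, schema published via pydantic)


class _NodeModel(BaseModel):
    id: str = Field(min_length=1)
    kind: NodeKind = NodeKind.LOCATION
    label: str = ""


class _EdgeModel(BaseModel):
    a: str
    b: str
    directed: bool = False


class GraphFileModel(BaseModel):
    """Schema of the graph JSON file.

    Edges are 2-item arrays ``["idA", "idB"]`` (undirected) or objects
    ``{"a": ..., "b": ..., "directed": true}`` for one-way passages.
    """

    nodes: list[_NodeModel]
    edges: list[list[str] | _EdgeModel] = []
    game_start_node: Optional[str] = None


class _ObjectiveModel(BaseModel):
    id: str = Field(min_length=1)
    target_node: str
    label: str = ""


class _TaskModel(BaseModel):
    id: str = Field(min_length=1)
    start_node: str
    objectives: list[_ObjectiveModel] = Field(min_length=1)
    manual_R: Optional[int] = Field(default=None, ge=1)


class TaskFileModel(BaseModel):
    tasks: list[_TaskModel]
    game_start_node: Optional[str] = None


GRAPH_FILE_SCHEMA = GraphFileModel.model_json_schema()
TASK_FILE_SCHEMA = TaskFileModel.model_json_schema()


def _read_json(path: str | Path) -> object:
    try:
        return json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc


def load_graph(path: str | Path) -> SpatialGraph:
    """Read and validate a graph JSON file."""
    raw = _read_json(path)
    try:
        model = GraphFileModel.model_validate(raw)
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    undirected: list[tuple[str, str]] = []
    directed: list[tuple[str, str]] = []
    for e in model.edges:
        if isinstance(e, _EdgeModel):
            (directed if e.directed else undirected).append((e.a, e.b))
        else:
            if len(e) != 2:
                raise SchemaError(f"{path}: edge {e!r} must have exactly 2 endpoints")
            undirected.append((e[0], e[1]))
    nodes = [Node(n.id, n.kind, n.label) for n in model.nodes]
    return SpatialGraph(
        nodes, undirected, directed, game_start_node=model.game_start_node
    )


def save_graph(graph: SpatialGraph, path: str | Path) -> None:
    undirected = set()
    payload_edges: list[object] = []
    for a, b in graph.edge_list():
        if graph.has_link(b, a):
            undirected.add((a, b))
            payload_edges.append([a, b])
        else:
            payload_edges.append({"a": a, "b": b, "directed": True})
    payload = {
        "nodes": [
            {"id": n.id, "kind": n.kind.value, "label": n.label}
            for n in sorted(graph.nodes.values(), key=lambda n: n.id)
        ],
        "edges": payload_edges,
        "game_start_node": graph.game_start_node,
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=False) + "\n", encoding="utf-8"
    )


def load_tasks(path: str | Path, graph: Optional[SpatialGraph] = None) -> TaskSet:
    """Read and validate a task JSON file.

    The game start node may come from the task file or, failing that, the
    graph file; it must exist somewhere.
    """
    raw = _read_json(path)
    try:
        model = TaskFileModel.model_validate(raw)
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    start = model.game_start_node
    if start is None and graph is not None:
        start = graph.game_start_node
    if start is None:
        raise SchemaError(f"{path}: no game_start_node in task or graph file")
    tasks = tuple(
        Task(
            id=t.id,
            start_node=t.start_node,
            objectives=tuple(
                Objective(o.id, o.target_node, o.label) for o in t.objectives
            ),
            manual_r=t.manual_R,
        )
        for t in model.tasks
    )
    task_set = TaskSet(tasks=tasks, game_start_node=start)
    if graph is not None:
        task_set.validate_against(graph)
    return task_set


def save_tasks(tasks: TaskSet, path: str | Path) -> None:
    payload = {
        "game_start_node": tasks.game_start_node,
        "tasks": [
            {
                "id": t.id,
                "start_node": t.start_node,
                "objectives": [
                    {"id": o.id, "target_node": o.target_node, "label": o.label}
                    for o in t.objectives
                ],
                **({"manual_R": t.manual_r} if t.manual_r is not None else {}),
            }
            for t in tasks.tasks
        ],
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=False) + "\n", encoding="utf-8"
    )
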