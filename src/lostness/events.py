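"""Player interaction logs: reading, validation, and segmentation.

A log is the ordered list of timestamped interactions one player made:
moving between nodes, picking up objects, inspecting them, and the
task/objective lifecycle events.  From it the package reconstructs the
path actually walked and reduces each analysis window to the count
triple (R, S, N) that the lostness statistic consumes:

* ``S`` — total node entries: every ``move`` event, plus every ``pickup``
  that changes the current node; ``inspect`` (turning an item in hand)
  never counts.
* ``N`` — distinct nodes among those entries, uniqueness local to the
  window and reset with it.
* ``R`` — the minimum entries needed, from the world model.

Two segmentations exist.  *Task windows* span task_start..task_complete;
events inside overlapping windows are counted in every open window (a
known property of the global measure, kept deliberately).  *Objective
segments* partition the whole session at successive objective
completions, starting from the game start node, with counters reset at
each completion.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .errors import (
    ParseError,
    StructuralError,
    UnknownIdentifierError,
)
from .metrics import PathCounts
from .world import (
    NodeKind,
    SpatialGraph,
    TaskSet,
    min_task_route,
    route_entry_counts,
    shortest_hops,
)

__all__ = [
    "EventKind",
    "NavigationEvent",
    "EventLog",
    "Diagnostic",
    "ObjectiveSegment",
    "TaskSegment",
    "read_log",
    "read_logs",
    "write_log",
    "validate_log",
    "segment_tasks",
    "segment_objectives",
]


class EventKind(str, Enum):
    MOVE = "move"
    PICKUP = "pickup"
    INSPECT = "inspect"
    TASK_START = "task_start"
    OBJECTIVE_COMPLETE = "objective_complete"
    TASK_COMPLETE = "task_complete"


_NODE_KINDS = {EventKind.MOVE, EventKind.PICKUP, EventKind.INSPECT}
_TASK_KINDS = {EventKind.TASK_START, EventKind.TASK_COMPLETE}


@dataclass(frozen=True)
class NavigationEvent:
    """One captured interaction.  ``seq`` breaks timestamp ties."""

    ts: datetime
    seq: int
    player: str
    kind: EventKind
    node: Optional[str] = None
    task: Optional[str] = None
    objective: Optional[str] = None
    extra: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.seq < 0:
            raise StructuralError("seq must be nonnegative")
        if self.kind in _NODE_KINDS and self.node is None:
            raise StructuralError(f"{self.kind.value} event requires a node id")
        if self.kind in _TASK_KINDS and self.task is None:
            raise StructuralError(f"{self.kind.value} event requires a task id")
        if self.kind is EventKind.OBJECTIVE_COMPLETE and (
            self.objective is None or self.node is None
        ):
            raise StructuralError(
                "objective_complete requires both an objective id and a node id"
            )

    @property
    def order_key(self) -> tuple[datetime, int]:
        return (self.ts, self.seq)


@dataclass(frozen=True)
class EventLog:
    """One player's ordered event stream.

    ``truncated`` marks a log cut off before all tasks completed (the
    simulator sets it when an agent hits its step budget).
    """

    player: str
    events: tuple[NavigationEvent, ...]
    truncated: bool = False

    def __post_init__(self) -> None:
        last = None
        for ev in self.events:
            if ev.player != self.player:
                raise StructuralError(
                    f"event for player {ev.player!r} in log of {self.player!r}"
                )
            if last is not None and ev.order_key <= last:
                raise StructuralError(
                    f"events not strictly increasing by (ts, seq) at {ev.order_key}"
                )
            last = ev.order_key

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[NavigationEvent]:
        return iter(self.events)


# ---------------------------------------------------------------------
# file I/O — canonical JSONL, CSV accepted


_REQUIRED = ("ts", "seq", "player", "kind")
_KNOWN = _REQUIRED + ("node", "task", "objective")


def _event_from_record(record: dict, line: int) -> NavigationEvent:
    for name in _REQUIRED:
        if record.get(name) in (None, ""):
            raise ParseError(f"missing required field {name!r}", line)
    try:
        ts = datetime.fromisoformat(str(record["ts"]))
    except ValueError:
        raise ParseError(f"malformed timestamp {record['ts']!r}", line) from None
    try:
        seq = int(record["seq"])
    except (TypeError, ValueError):
        raise ParseError(f"malformed seq {record['seq']!r}", line) from None
    try:
        kind = EventKind(record["kind"])
    except ValueError:
        raise ParseError(f"unknown event kind {record['kind']!r}", line) from None

    def opt(name: str) -> Optional[str]:
        value = record.get(name)
        return None if value in (None, "") else str(value)

    extra = tuple(
        sorted((k, v) for k, v in record.items() if k not in _KNOWN and v not in (None, ""))
    )
    try:
        return NavigationEvent(
            ts=ts,
            seq=seq,
            player=str(record["player"]),
            kind=kind,
            node=opt("node"),
            task=opt("task"),
            objective=opt("objective"),
            extra=extra,
        )
    except StructuralError as exc:
        raise ParseError(str(exc), line) from exc


def _iter_records(source: str | Path) -> Iterator[tuple[int, dict]]:
    path = Path(source)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".csv":
        reader = csv.DictReader(text.splitlines())
        for i, row in enumerate(reader, start=2):  # header is line 1
            yield i, row
    else:
        for i, raw in enumerate(text.splitlines(), start=1):
            if not raw.strip():
                continue
            try:
                record = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise ParseError(f"not valid JSON: {exc.msg}", i) from exc
            if not isinstance(record, dict):
                raise ParseError("each line must be a JSON object", i)
            yield i, record


def read_logs(source: str | Path) -> list[EventLog]:
    """Read a JSONL or CSV event file that may interleave several players.

    Each player's events must already be strictly ordered by (ts, seq);
    a violation is a parse error at the offending line.
    """
    per_player: dict[str, list[NavigationEvent]] = {}
    last_key: dict[str, tuple] = {}
    for line, record in _iter_records(source):
        ev = _event_from_record(record, line)
        prev = last_key.get(ev.player)
        if prev is not None and ev.order_key <= prev:
            raise ParseError(
                f"duplicate or out-of-order (ts, seq) {ev.order_key} for "
                f"player {ev.player!r}",
                line,
            )
        last_key[ev.player] = ev.order_key
        per_player.setdefault(ev.player, []).append(ev)
    return [
        EventLog(player=p, events=tuple(evs)) for p, evs in per_player.items()
    ]


def read_log(source: str | Path) -> EventLog:
    """Read a single-player event file (empty file → empty anonymous log)."""
    logs = read_logs(source)
    if not logs:
        return EventLog(player="", events=())
    if len(logs) > 1:
        raise ParseError(
            f"expected a single player, found {sorted(l.player for l in logs)}"
        )
    return logs[0]


def _event_payload(ev: NavigationEvent) -> dict:
    payload: dict = {
        "ts": ev.ts.isoformat(),
        "seq": ev.seq,
        "player": ev.player,
        "kind": ev.kind.value,
    }
    for name in ("node", "task", "objective"):
        value = getattr(ev, name)
        if value is not None:
            payload[name] = value
    payload.update(dict(ev.extra))
    return payload


def write_log(log: EventLog | Iterable[EventLog], path: str | Path) -> None:
    """Write the canonical form: UTF-8 JSONL, one event per line, fields in
    fixed order, events sorted by (ts, seq).  Re-reading and re-writing
    reproduces the bytes exactly."""
    logs = [log] if isinstance(log, EventLog) else list(log)
    lines = []
    for one in logs:
        for ev in one.events:
            lines.append(
                json.dumps(_event_payload(ev), ensure_ascii=False, separators=(",", ":"))
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Diagnostic:
    """One consistency finding; ``index`` is the event's position in the log."""

    code: str
    message: str
    index: int

    def __str__(self) -> str:
        return f"[{self.code}] event {self.index}: {self.message}"


def validate_log(
    log: EventLog, graph: SpatialGraph, tasks: TaskSet
) -> list[Diagnostic]:
    """Cross-check a log against the world model.  Diagnostic, never raises.

    Flags: moves between unlinked nodes (teleports), unresolvable ids,
    objectives completed away from their target node, and tasks completed
    before all their objectives.
    """
    out: list[Diagnostic] = []
    current = tasks.game_start_node
    known_objectives = {o.id: o for t in tasks.tasks for o in t.objectives}
    objectives_by_task = {t.id: {o.id for o in t.objectives} for t in tasks.tasks}
    completed: set[str] = set()
    for i, ev in enumerate(log.events):
        if ev.node is not None and ev.node not in graph:
            out.append(Diagnostic("unknown_node", f"unknown node {ev.node!r}", i))
            continue
        if ev.kind in _NODE_KINDS:
            if ev.node != current and not graph.has_link(current, ev.node):
                out.append(
                    Diagnostic(
                        "teleport",
                        f"{ev.kind.value} from {current!r} to unlinked {ev.node!r}",
                        i,
                    )
                )
            current = ev.node
        elif ev.kind in _TASK_KINDS:
            if ev.task not in objectives_by_task:
                out.append(Diagnostic("unknown_task", f"unknown task {ev.task!r}", i))
            elif ev.kind is EventKind.TASK_COMPLETE:
                missing = objectives_by_task[ev.task] - completed
                if missing:
                    out.append(
                        Diagnostic(
                            "premature_task_complete",
                            f"task {ev.task!r} completed with unmet objectives "
                            f"{sorted(missing)}",
                            i,
                        )
                    )
        elif ev.kind is EventKind.OBJECTIVE_COMPLETE:
            obj = known_objectives.get(ev.objective)
            if obj is None:
                out.append(
                    Diagnostic(
                        "unknown_objective", f"unknown objective {ev.objective!r}", i
                    )
                )
                continue
            completed.add(ev.objective)
            if ev.node != obj.target_node:
                out.append(
                    Diagnostic(
                        "objective_node_mismatch",
                        f"objective {ev.objective!r} completed at {ev.node!r}, "
                        f"target is {obj.target_node!r}",
                        i,
                    )
                )
    return out


# ---------------------------------------------------------------------
# segmentation


@dataclass(frozen=True)
class TaskSegment:
    """Counts over one completed task window."""

    task: str
    counts: PathCounts
    objective_count: int


@dataclass(frozen=True)
class ObjectiveSegment:
    """Counts between two successive objective completions."""

    objective: str
    counts: PathCounts
    start_node: str
    end_node: str

    @property
    def degenerate(self) -> bool:
        """No movement occurred; the per-segment lostness is undefined and
        the segment contributes zeros to the summed local measure."""
        return self.counts.S == 0 or self.counts.N == 0


def _counted_entries(
    log: EventLog, count_kinds: Optional[frozenset[NodeKind]], graph: SpatialGraph
) -> Iterator[tuple[int, NavigationEvent, Optional[str]]]:
    """Yield (index, event, entered-node-or-None) applying the entry rule.

    ``count_kinds`` optionally restricts which node kinds count as
    entries (e.g. locations only); ``None`` counts every kind.
    """
    current: Optional[str] = None
    for i, ev in enumerate(log.events):
        entered: Optional[str] = None
        if ev.kind is EventKind.MOVE:
            entered = ev.node
        elif ev.kind is EventKind.PICKUP and ev.node != current:
            entered = ev.node
        if ev.kind in _NODE_KINDS:
            current = ev.node
        if entered is not None and count_kinds is not None:
            if entered in graph and graph.kind_of(entered) not in count_kinds:
                entered = None
        yield i, ev, entered


def segment_tasks(
    log: EventLog,
    graph: SpatialGraph,
    tasks: TaskSet,
    count_kinds: Optional[Iterable[NodeKind]] = None,
) -> list[TaskSegment]:
    """One segment per *completed* task, in completion order.

    S counts node entries inside the [task_start, task_complete] window,
    N the distinct nodes among them; overlapping windows each count the
    same events.  R comes from the minimum task route (or the configured
    manual value).
    """
    kinds = frozenset(count_kinds) if count_kinds is not None else None
    open_windows: dict[str, tuple[int, set[str]]] = {}
    totals: dict[str, int] = {}
    out: list[TaskSegment] = []
    for i, ev, entered in _counted_entries(log, kinds, graph):
        if entered is not None:
            for task_id in open_windows:
                seen = open_windows[task_id][1]
                totals[task_id] += 1
                seen.add(entered)
        if ev.kind is EventKind.TASK_START:
            task = tasks.task(ev.task)
            if ev.task in open_windows:
                raise StructuralError(
                    f"task {ev.task!r} started again while still open (event {i})"
                )
            open_windows[ev.task] = (i, set())
            totals[ev.task] = 0
        elif ev.kind is EventKind.TASK_COMPLETE:
            task = tasks.task(ev.task)
            if ev.task not in open_windows:
                raise StructuralError(
                    f"task {ev.task!r} completed without a matching start (event {i})"
                )
            _, seen = open_windows.pop(ev.task)
            manual = tasks.manual_r_for(task)
            if manual is not None:
                r = min_task_route(
                    graph, task.start_node, task.target_nodes, manual_override=manual
                )
            else:
                # distinct entries of the optimal route: the walker's N can
                # never undercut it, keeping R <= N for completed windows
                _, r, _ = route_entry_counts(
                    graph, task.start_node, task.target_nodes
                )
            out.append(
                TaskSegment(
                    task=ev.task,
                    counts=PathCounts(R=r, S=totals.pop(ev.task), N=len(seen)),
                    objective_count=task.objective_count,
                )
            )
    return out


def segment_objectives(
    log: EventLog,
    graph: SpatialGraph,
    tasks: TaskSet,
    count_kinds: Optional[Iterable[NodeKind]] = None,
) -> list[ObjectiveSegment]:
    """Partition the session at successive objective completions.

    The first segment starts at the game start node; each later one at
    the node where the previous objective completed.  R is the BFS
    shortest-path length between those anchors; S and N are counted from
    the events inside the segment, counters resetting at each completion.
    Events after the final completion belong to no segment.
    """
    kinds = frozenset(count_kinds) if count_kinds is not None else None
    seg_start = tasks.game_start_node
    s_count = 0
    seen: set[str] = set()
    completed: set[str] = set()
    out: list[ObjectiveSegment] = []
    for i, ev, entered in _counted_entries(log, kinds, graph):
        if entered is not None:
            s_count += 1
            seen.add(entered)
        if ev.kind is EventKind.OBJECTIVE_COMPLETE:
            tasks.objective(ev.objective)  # resolve or raise
            if ev.objective in completed:
                raise StructuralError(
                    f"objective {ev.objective!r} completed twice (event {i})"
                )
            completed.add(ev.objective)
            r = shortest_hops(graph, seg_start, ev.node)
            out.append(
                ObjectiveSegment(
                    objective=ev.objective,
                    counts=PathCounts(R=r, S=s_count, N=len(seen)),
                    start_node=seg_start,
                    end_node=ev.node,
                )
            )
            seg_start = ev.node
            s_count = 0
            seen = set()
    return out
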