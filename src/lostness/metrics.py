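"""The lostness statistic and its global and local aggregates.

For one navigation segment with minimum entries R, total entries S and
unique entries N, lostness is

    L = (N/S - 1)^2 + (R/N - 1)^2

a value in [0, 2): 0 means the segment was walked perfectly (R = S = N),
the first addend grows with *repetition* (revisiting nodes), the second
with *detours* (visiting nodes the minimum route does not need).

Two whole-session aggregates:

* **Global** L_G — lostness per completed task window, averaged with
  weights x_t = the task's objective count, so complex tasks are not
  masked by simple ones.
* **Local** L_L — R, S, N summed over objective-to-objective segments
  (counters reset at each completion), the formula applied once to the
  summed triple; equivalently the whole game treated as one long task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence, Union

from .errors import (
    DegenerateSegmentError,
    InconsistentCountsError,
    InsufficientDataError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .events import EventLog, ObjectiveSegment, TaskSegment
    from .world import NodeKind, SpatialGraph, TaskSet

__all__ = [
    "PathCounts",
    "LostnessResult",
    "GlobalLostnessResult",
    "LocalLostnessResult",
    "PlayerReport",
    "lostness",
    "global_lostness",
    "local_lostness",
    "player_report",
]


@dataclass(frozen=True)
class PathCounts:
    """The (R, S, N) triple for one segment: minimum / total / unique
    node entries.  N can never exceed S; R is whatever the world model
    (or a manual override) says is needed."""

    R: int
    S: int
    N: int

    def __post_init__(self) -> None:
        if min(self.R, self.S, self.N) < 0:
            raise InconsistentCountsError(f"negative counts in {self}")
        if self.N > self.S:
            raise InconsistentCountsError(
                f"unique entries N={self.N} exceed total entries S={self.S}"
            )

    def __add__(self, other: "PathCounts") -> "PathCounts":
        return PathCounts(self.R + other.R, self.S + other.S, self.N + other.N)


@dataclass(frozen=True)
class LostnessResult:
    """L with its two addends reported separately."""

    value: float
    repetition_term: float
    detour_term: float


@dataclass(frozen=True)
class GlobalLostnessResult:
    #: (task id, L_t or None when undefined, weight x_t)
    per_task: tuple[tuple[str, Optional[float], int], ...]
    value: float


@dataclass(frozen=True)
class LocalLostnessResult:
    #: (objective id, L_o or None for a degenerate no-movement segment)
    per_objective: tuple[tuple[str, Optional[float]], ...]
    summed: PathCounts
    value: float


def lostness(counts: PathCounts) -> LostnessResult:
    """Evaluate the lostness formula on one count triple.

    Raises :class:`DegenerateSegmentError` when S or N is zero (no
    movement — callers should apply the skip rule instead of scoring),
    and :class:`InconsistentCountsError` when R > N, which no real
    completed path can produce but a bad manual R can.
    """
    if counts.S == 0 or counts.N == 0:
        raise DegenerateSegmentError(
            f"lostness undefined for {counts}: no node entries; degenerate "
            "segments contribute zeros to summed measures and are flagged"
        )
    if counts.R > counts.N:
        raise InconsistentCountsError(
            f"R={counts.R} exceeds unique entries N={counts.N}; a walked path "
            "that reaches its goal visits at least R distinct nodes"
        )
    repetition = (counts.N / counts.S - 1.0) ** 2
    detour = (counts.R / counts.N - 1.0) ** 2
    return LostnessResult(
        value=repetition + detour, repetition_term=repetition, detour_term=detour
    )


def global_lostness(
    task_results: Sequence[Union[tuple[float, int], tuple[str, Optional[float], int]]],
) -> GlobalLostnessResult:
    """Objective-count-weighted mean of per-task lostness values.

    Accepts (L_t, x_t) pairs or (task id, L_t, x_t) triples; entries with
    ``L_t = None`` (degenerate windows) keep their place in the breakdown
    but carry no weight.
    """
    if not task_results:
        raise InsufficientDataError(
            "no completed tasks: global lostness is undefined"
        )
    normalized: list[tuple[str, Optional[float], int]] = []
    for i, item in enumerate(task_results):
        if len(item) == 2:
            value, weight = item  # type: ignore[misc]
            task_id = f"task{i}"
        else:
            task_id, value, weight = item  # type: ignore[misc]
        if weight < 1:
            raise InconsistentCountsError(f"weight x_t must be >= 1, got {weight}")
        if value is not None and not 0.0 <= value <= 2.0:
            raise InconsistentCountsError(f"task lostness {value} outside [0, 2]")
        normalized.append((str(task_id), value, int(weight)))
    scored = [(v, x) for _, v, x in normalized if v is not None]
    if not scored:
        raise DegenerateSegmentError("every task window is degenerate")
    total_weight = sum(x for _, x in scored)
    value = sum(v * x for v, x in scored) / total_weight
    return GlobalLostnessResult(per_task=tuple(normalized), value=value)


def local_lostness(
    segments: Sequence[Union["ObjectiveSegment", PathCounts]],
) -> LocalLostnessResult:
    """Sum R, S, N over objective segments, then apply the formula once.

    Degenerate segments (no movement) add zeros to the sums and are
    flagged (``None``) in the per-objective breakdown so "no navigation"
    cannot read as "perfect navigation".
    """
    if not segments:
        raise InsufficientDataError(
            "no completed objectives: local lostness is undefined"
        )
    total = PathCounts(0, 0, 0)
    per_objective: list[tuple[str, Optional[float]]] = []
    for i, seg in enumerate(segments):
        counts = seg if isinstance(seg, PathCounts) else seg.counts
        name = getattr(seg, "objective", f"objective{i}")
        total = total + counts
        if counts.S == 0 or counts.N == 0:
            per_objective.append((name, None))
        else:
            per_objective.append((name, lostness(counts).value))
    if total.S == 0 or total.N == 0:
        raise DegenerateSegmentError(
            "all segments are degenerate: no navigation to score"
        )
    return LocalLostnessResult(
        per_objective=tuple(per_objective),
        summed=total,
        value=lostness(total).value,
    )


@dataclass(frozen=True)
class PlayerReport:
    """Both measures for one player, with provenance."""

    player: str
    global_result: Optional[GlobalLostnessResult]
    local_result: Optional[LocalLostnessResult]
    #: task ids started or defined but never completed in this log
    incomplete_tasks: tuple[str, ...]
    diagnostics: tuple
    truncated: bool

    @property
    def global_value(self) -> float:
        return self.global_result.value if self.global_result else math.nan

    @property
    def local_value(self) -> float:
        return self.local_result.value if self.local_result else math.nan

    @property
    def complete(self) -> bool:
        return not self.incomplete_tasks and not self.truncated


def player_report(
    log: "EventLog",
    graph: "SpatialGraph",
    tasks: "TaskSet",
    count_kinds: Optional[Sequence["NodeKind"]] = None,
    strict: bool = False,
) -> PlayerReport:
    """Segment one player's log and compute both measures.

    Incomplete tasks are excluded from the global weighted mean and
    listed on the report; with ``strict=True`` they raise instead.
    Returns ``None`` in place of a measure that has no completed
    window/segment to score.
    """
    from .events import segment_objectives, segment_tasks, validate_log

    diagnostics = validate_log(log, graph, tasks)
    task_segments = segment_tasks(log, graph, tasks, count_kinds=count_kinds)
    objective_segments = segment_objectives(log, graph, tasks, count_kinds=count_kinds)

    completed = {seg.task for seg in task_segments}
    incomplete = tuple(t for t in tasks.task_ids if t not in completed)
    if strict and incomplete:
        raise InsufficientDataError(
            f"incomplete tasks in strict mode: {list(incomplete)}"
        )

    global_result: Optional[GlobalLostnessResult] = None
    if task_segments:
        per_task: list[tuple[str, Optional[float], int]] = []
        for seg in task_segments:
            if seg.counts.S == 0 or seg.counts.N == 0:
                per_task.append((seg.task, None, seg.objective_count))
            else:
                try:
                    value = lostness(seg.counts).value
                except InconsistentCountsError:
                    # a manual R above the walker's unique entries, or an
                    # equal-length route with fewer distinct nodes: flag
                    # the window rather than score it
                    value = None
                per_task.append((seg.task, value, seg.objective_count))
        try:
            global_result = global_lostness(per_task)
        except DegenerateSegmentError:
            global_result = None

    local_result: Optional[LocalLostnessResult] = None
    if objective_segments:
        try:
            local_result = local_lostness(objective_segments)
        except DegenerateSegmentError:
            local_result = None

    return PlayerReport(
        player=log.player,
        global_result=global_result,
        local_result=local_result,
        incomplete_tasks=incomplete,
        diagnostics=tuple(diagnostics),
        truncated=log.truncated,
    )
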