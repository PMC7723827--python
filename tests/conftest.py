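"""Shared fixtures: small hand-built worlds and a log builder."""

from datetime import datetime, timedelta

import pytest

from lostness.events import EventKind, EventLog, NavigationEvent
from lostness.world import Node, NodeKind, Objective, SpatialGraph, Task, TaskSet

EPOCH = datetime(2021, 6, 1)


def make_log(player: str, steps, truncated: bool = False) -> EventLog:
    """Build a log from shorthand tuples.

    Each step is (kind, node) or (kind, node, task_or_objective); ts/seq
    are assigned automatically, one second apart.
    """
    events = []
    for i, step in enumerate(steps):
        kind = EventKind(step[0])
        node = step[1]
        ref = step[2] if len(step) > 2 else None
        events.append(
            NavigationEvent(
                ts=EPOCH + timedelta(seconds=i),
                seq=i,
                player=player,
                kind=kind,
                node=node,
                task=ref if kind in (EventKind.TASK_START, EventKind.TASK_COMPLETE) else None,
                objective=ref if kind is EventKind.OBJECTIVE_COMPLETE else None,
            )
        )
    return EventLog(player=player, events=tuple(events), truncated=truncated)


@pytest.fixture
def log_builder():
    return make_log


@pytest.fixture
def path_world():
    """A 5-room corridor A-B-C-D-E with one task: find C, then E.

    A perfect playthrough walks A→B→C→D→E with no revisits, so both
    lostness measures are exactly zero on it.
    """
    nodes = [Node(x, NodeKind.LOCATION) for x in "ABCDE"]
    graph = SpatialGraph(
        nodes,
        edges=[("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")],
        game_start_node="A",
    )
    tasks = TaskSet(
        tasks=(
            Task(
                id="t1",
                start_node="A",
                objectives=(
                    Objective("o1", target_node="C"),
                    Objective("o2", target_node="E"),
                ),
            ),
        ),
        game_start_node="A",
    )
    tasks.validate_against(graph)
    return graph, tasks


@pytest.fixture
def perfect_path_log(path_world):
    return make_log(
        "p1",
        [
            ("task_start", "A", "t1"),
            ("move", "B"),
            ("move", "C"),
            ("objective_complete", "C", "o1"),
            ("move", "D"),
            ("move", "E"),
            ("objective_complete", "E", "o2"),
            ("task_complete", "E", "t1"),
        ],
    )


@pytest.fixture
def star_world():
    """Hub H with three leaves; visiting two leaves from the hub needs
    1 + 1 + 1 = 3 entries however ordered."""
    nodes = [Node("H")] + [Node(f"L{i}") for i in range(3)]
    graph = SpatialGraph(
        nodes, edges=[("H", "L0"), ("H", "L1"), ("H", "L2")], game_start_node="H"
    )
    return graph


@pytest.fixture(scope="session")
def sim_world():
    from lostness.simulate import generate_world

    return generate_world(seed=7)
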