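"""Event logs: I/O, validation diagnostics, and segmentation counts."""

import json

import pytest

from lostness.errors import ParseError, StructuralError
from lostness.events import (
    EventKind,
    EventLog,
    read_log,
    read_logs,
    segment_objectives,
    segment_tasks,
    validate_log,
    write_log,
)
from lostness.metrics import PathCounts
from lostness.simulate import AgentConfig, simulate_playthrough
from lostness.world import NodeKind


class TestLogIO:
    def test_empty_file_gives_empty_log(self, tmp_path):
        p = tmp_path / "empty.jsonl"
        p.write_text("")
        log = read_log(p)
        assert len(log) == 0

    def test_round_trip_is_byte_identical(self, tmp_path, sim_world):
        graph, tasks = sim_world
        log = simulate_playthrough(
            graph, tasks, AgentConfig(wander_prob=0.4, seed=5, player="p9")
        )
        assert len(log) >= 60
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_log(log, p1)
        back = read_log(p1)
        write_log(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert back.events == log.events

    def test_out_of_order_timestamps_rejected_with_line(self, tmp_path):
        lines = [
            {"ts": "2021-01-01T00:00:02", "seq": 0, "player": "p", "kind": "move", "node": "A"},
            {"ts": "2021-01-01T00:00:01", "seq": 1, "player": "p", "kind": "move", "node": "B"},
        ]
        p = tmp_path / "bad.jsonl"
        p.write_text("\n".join(json.dumps(l) for l in lines))
        with pytest.raises(ParseError, match="line 2"):
            read_log(p)

    def test_duplicate_ts_seq_rejected(self, tmp_path):
        row = {"ts": "2021-01-01T00:00:01", "seq": 3, "player": "p", "kind": "move", "node": "A"}
        p = tmp_path / "dup.jsonl"
        p.write_text(json.dumps(row) + "\n" + json.dumps(row))
        with pytest.raises(ParseError, match="line 2"):
            read_log(p)

    @pytest.mark.parametrize(
        "mutation, message",
        [
            ({"ts": "yesterday-ish"}, "malformed timestamp"),
            ({"kind": "teleport"}, "unknown event kind"),
            ({"player": ""}, "missing required field"),
            ({"node": None}, "requires a node"),
        ],
    )
    def test_malformed_rows_name_the_line(self, tmp_path, mutation, message):
        row = {"ts": "2021-01-01T00:00:01", "seq": 0, "player": "p", "kind": "move", "node": "A"}
        row.update(mutation)
        p = tmp_path / "bad.jsonl"
        p.write_text(json.dumps(row))
        with pytest.raises(ParseError, match=message):
            read_log(p)

    def test_csv_and_jsonl_agree(self, tmp_path):
        p_csv = tmp_path / "log.csv"
        p_csv.write_text(
            "ts,seq,player,kind,node,task,objective\n"
            "2021-01-01T00:00:00,0,p,task_start,A,t1,\n"
            "2021-01-01T00:00:01,1,p,move,B,,\n"
        )
        p_jsonl = tmp_path / "log.jsonl"
        p_jsonl.write_text(
            json.dumps({"ts": "2021-01-01T00:00:00", "seq": 0, "player": "p", "kind": "task_start", "node": "A", "task": "t1"})
            + "\n"
            + json.dumps({"ts": "2021-01-01T00:00:01", "seq": 1, "player": "p", "kind": "move", "node": "B"})
        )
        assert read_log(p_csv).events == read_log(p_jsonl).events

    def test_unknown_columns_preserved_through_round_trip(self, tmp_path):
        row = {
            "ts": "2021-01-01T00:00:00", "seq": 0, "player": "p",
            "kind": "move", "node": "A", "fps": 59.8,
        }
        p = tmp_path / "x.jsonl"
        p.write_text(json.dumps(row))
        log = read_log(p)
        assert dict(log.events[0].extra) == {"fps": 59.8}
        write_log(log, p)
        assert json.loads(p.read_text())["fps"] == 59.8

    def test_multi_player_file_splits(self, tmp_path):
        rows = [
            {"ts": "2021-01-01T00:00:00", "seq": 0, "player": "a", "kind": "move", "node": "A"},
            {"ts": "2021-01-01T00:00:00", "seq": 0, "player": "b", "kind": "move", "node": "B"},
        ]
        p = tmp_path / "two.jsonl"
        p.write_text("\n".join(json.dumps(r) for r in rows))
        logs = read_logs(p)
        assert sorted(l.player for l in logs) == ["a", "b"]
        with pytest.raises(ParseError, match="single player"):
            read_log(p)


class TestValidateLog:
    def test_perfect_playthrough_is_clean(self, path_world, perfect_path_log):
        graph, tasks = path_world
        assert validate_log(perfect_path_log, graph, tasks) == []

    def test_simulated_logs_are_clean(self, sim_world):
        graph, tasks = sim_world
        for seed in range(5):
            log = simulate_playthrough(
                graph, tasks, AgentConfig(wander_prob=0.3, seed=seed)
            )
            assert validate_log(log, graph, tasks) == []

    def test_teleport_flagged(self, path_world, log_builder):
        graph, tasks = path_world
        log = log_builder("p", [("move", "B"), ("move", "D")])  # B-D not linked
        diags = validate_log(log, graph, tasks)
        assert [d.code for d in diags] == ["teleport"]
        assert diags[0].index == 1

    def test_objective_completed_at_wrong_node(self, path_world, log_builder):
        graph, tasks = path_world
        log = log_builder("p", [("move", "B"), ("objective_complete", "B", "o1")])
        codes = [d.code for d in validate_log(log, graph, tasks)]
        assert codes == ["objective_node_mismatch"]

    def test_premature_task_complete_and_unknown_ids(self, path_world, log_builder):
        graph, tasks = path_world
        log = log_builder(
            "p",
            [
                ("task_start", "A", "t1"),
                ("move", "Z"),
                ("task_complete", "A", "t1"),
                ("task_start", "A", "ghost"),
            ],
        )
        codes = [d.code for d in validate_log(log, graph, tasks)]
        assert codes == ["unknown_node", "premature_task_complete", "unknown_task"]


class TestSegmentTasks:
    def test_perfect_playthrough_counts_match_minimum(self, path_world, perfect_path_log):
        graph, tasks = path_world
        [seg] = segment_tasks(perfect_path_log, graph, tasks)
        assert seg.counts == PathCounts(R=4, S=4, N=4)
        assert seg.objective_count == 2

    def test_revisits_counted_in_s_not_n(self, path_world, log_builder):
        graph, tasks = path_world
        log = log_builder(
            "p",
            [
                ("task_start", "A", "t1"),
                ("move", "B"), ("move", "A"), ("move", "B"), ("move", "A"),
                ("move", "B"), ("move", "C"),
                ("objective_complete", "C", "o1"),
                ("move", "D"), ("move", "E"),
                ("objective_complete", "E", "o2"),
                ("task_complete", "E", "t1"),
            ],
        )
        [seg] = segment_tasks(log, graph, tasks)
        # entries B,A,B,A,B,C,D,E: 8 total, 5 unique
        assert (seg.counts.S, seg.counts.N) == (8, 5)

    def test_no_completion_yields_no_segment(self, path_world, log_builder):
        graph, tasks = path_world
        log = log_builder("p", [("task_start", "A", "t1"), ("move", "B")])
        assert segment_tasks(log, graph, tasks) == []

    def test_complete_without_start_is_structural(self, path_world, log_builder):
        graph, tasks = path_world
        log = log_builder("p", [("task_complete", "A", "t1")])
        with pytest.raises(StructuralError, match="without a matching start"):
            segment_tasks(log, graph, tasks)

    def test_overlapping_windows_each_count_shared_events(self, log_builder):
        from lostness.world import Node, Objective, SpatialGraph, Task, TaskSet

        graph = SpatialGraph(
            [Node(x) for x in "ABC"], edges=[("A", "B"), ("B", "C")], game_start_node="A"
        )
        tasks = TaskSet(
            tasks=(
                Task("t1", "A", (Objective("o1", "B"),)),
                Task("t2", "A", (Objective("o2", "C"),)),
            ),
            game_start_node="A",
        )
        log = log_builder(
            "p",
            [
                ("task_start", "A", "t1"),
                ("task_start", "A", "t2"),
                ("move", "B"),
                ("objective_complete", "B", "o1"),
                ("task_complete", "B", "t1"),
                ("move", "C"),
                ("objective_complete", "C", "o2"),
                ("task_complete", "C", "t2"),
            ],
        )
        segs = {s.task: s.counts for s in segment_tasks(log, graph, tasks)}
        assert segs["t1"] == PathCounts(R=1, S=1, N=1)
        # t2's window also saw the move to B made for t1
        assert segs["t2"] == PathCounts(R=2, S=2, N=2)

    def test_inspect_never_counts(self, path_world, log_builder):
        graph, tasks = path_world
        log = log_builder(
            "p",
            [
                ("task_start", "A", "t1"),
                ("move", "B"), ("inspect", "B"), ("inspect", "B"),
                ("move", "C"), ("objective_complete", "C", "o1"),
                ("move", "D"), ("move", "E"), ("objective_complete", "E", "o2"),
                ("task_complete", "E", "t1"),
            ],
        )
        [seg] = segment_tasks(log, graph, tasks)
        assert seg.counts == PathCounts(R=4, S=4, N=4)


class TestSegmentObjectives:
    def test_perfect_segments_have_equal_counts(self, path_world, perfect_path_log):
        graph, tasks = path_world
        segs = segment_objectives(perfect_path_log, graph, tasks)
        assert [s.objective for s in segs] == ["o1", "o2"]
        assert segs[0].counts == PathCounts(R=2, S=2, N=2)
        assert segs[1].counts == PathCounts(R=2, S=2, N=2)
        assert segs[0].start_node == "A" and segs[1].start_node == "C"

    def test_consecutive_completions_at_same_node_are_degenerate(
        self, path_world, log_builder
    ):
        graph, tasks = path_world
        log = log_builder(
            "p",
            [
                ("move", "B"), ("move", "C"),
                ("objective_complete", "C", "o1"),
                ("objective_complete", "C", "o2"),
            ],
        )
        segs = segment_objectives(log, graph, tasks)
        assert segs[1].counts == PathCounts(0, 0, 0)
        assert segs[1].degenerate

    def test_no_completions_no_segments(self, path_world, log_builder):
        graph, tasks = path_world
        log = log_builder("p", [("move", "B")])
        assert segment_objectives(log, graph, tasks) == []

    def test_double_completion_is_structural(self, path_world, log_builder):
        graph, tasks = path_world
        log = log_builder(
            "p",
            [
                ("move", "B"), ("move", "C"),
                ("objective_complete", "C", "o1"),
                ("objective_complete", "C", "o1"),
            ],
        )
        with pytest.raises(StructuralError, match="twice"):
            segment_objectives(log, graph, tasks)

    def test_segments_tile_the_session(self, sim_world):
        """Sum of S over segments equals all counted entries up to the
        last objective completion."""
        graph, tasks = sim_world
        for seed in (1, 2, 3):
            log = simulate_playthrough(
                graph, tasks, AgentConfig(wander_prob=0.5, explore_rate=3.0, seed=seed)
            )
            segs = segment_objectives(log, graph, tasks)
            last = max(
                i for i, ev in enumerate(log.events)
                if ev.kind is EventKind.OBJECTIVE_COMPLETE
            )
            current = None
            entries = 0
            for ev in log.events[: last + 1]:
                if ev.kind is EventKind.MOVE:
                    entries += 1
                elif ev.kind is EventKind.PICKUP and ev.node != current:
                    entries += 1
                if ev.kind in (EventKind.MOVE, EventKind.PICKUP, EventKind.INSPECT):
                    current = ev.node
            assert sum(s.counts.S for s in segs) == entries

    def test_movement_reached_segments_satisfy_count_ordering(self, sim_world):
        graph, tasks = sim_world
        log = simulate_playthrough(
            graph, tasks, AgentConfig(wander_prob=0.6, seed=9)
        )
        for seg in segment_objectives(log, graph, tasks):
            assert seg.counts.S >= seg.counts.N
            if not seg.degenerate:
                assert seg.counts.N >= seg.counts.R

    def test_location_only_counting_drops_item_entries(self, sim_world):
        graph, tasks = sim_world
        log = simulate_playthrough(graph, tasks, AgentConfig(wander_prob=0.0, seed=3))
        full = segment_objectives(log, graph, tasks)
        loc_only = segment_objectives(
            log, graph, tasks, count_kinds=[NodeKind.LOCATION]
        )
        assert sum(s.counts.S for s in loc_only) < sum(s.counts.S for s in full)
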