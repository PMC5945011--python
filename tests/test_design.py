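from __future__ import annotations

import itertools

import numpy as np
import pytest

from racestop.design import (
    ConstraintError,
    CounterbalanceAssignment,
    ScheduleEntry,
    build_design,
    build_practice,
    default_assignments,
    randomize_block,
    read_schedule,
    validate_design,
    write_schedule,
)
from racestop.stimuli import StimulusItem, bundled_practice_stimuli


def _entry(picture, condition, trial_type="go", ssd=None, block=1, pos=1):
    return ScheduleEntry("p01", block, pos, picture, condition, trial_type, ssd)


class TestScheduleEntry:
    def test_ssd_required_iff_stop(self):
        with pytest.raises(ValueError):
            _entry("been", "related", "go", ssd=250)
        with pytest.raises(ValueError):
            _entry("been", "related", "stop", ssd=None)

    def test_rejects_unknown_condition(self):
        with pytest.raises(ValueError):
            _entry("been", "semi-related")


class TestBuildDesign:
    def test_total_and_block_counts(self, schedule):
        assert len(schedule) == 320
        for b in range(1, 5):
            block = [e for e in schedule if e.block == b]
            assert len(block) == 80
            assert sum(e.trial_type == "go" for e in block) == 60
            assert sum(e.trial_type == "stop" for e in block) == 20
            stops = [e for e in block if e.trial_type == "stop"]
            assert sum(e.condition == "related" for e in stops) == 10
            assert sum(e.ssd_ms == 250 for e in stops) == 10
            assert sum(e.ssd_ms == 325 for e in stops) == 10

    def test_stop_fraction_is_25_percent(self, schedule):
        assert sum(e.trial_type == "stop" for e in schedule) / len(schedule) == 0.25

    def test_each_picture_condition_stop_exactly_once(self, schedule):
        seen = {}
        for e in schedule:
            if e.trial_type == "stop":
                seen.setdefault((e.picture, e.condition), []).append(e.ssd_ms)
        assert len(seen) == 80
        assert all(len(v) == 1 for v in seen.values())

    def test_ssd_follows_assignment(self, schedule, assignments):
        for e in schedule:
            if e.trial_type == "stop":
                assert e.ssd_ms == assignments[0].ssd_for(e.picture)

    def test_wrong_stimulus_count_rejected(self, stimuli, assignments):
        with pytest.raises(ValueError, match="40"):
            build_design(stimuli[:39], assignments[0], seed=1)

    def test_non_partition_assignment_rejected(self, stimuli):
        names = sorted(it.picture_name for it in stimuli)
        bad = CounterbalanceAssignment(frozenset(names[:19]), frozenset(names[19:]))
        with pytest.raises(ValueError, match="equal disjoint"):
            build_design(stimuli, bad, seed=1)

    def test_deterministic_given_seed(self, stimuli, assignments):
        a = build_design(stimuli, assignments[0], seed=99)
        b = build_design(stimuli, assignments[0], seed=99)
        assert a == b

    @pytest.mark.parametrize("seed", range(8))
    def test_output_always_validates(self, stimuli, assignments, seed):
        schedule = build_design(stimuli, assignments[seed % 2], seed=seed)
        report = validate_design(schedule, stimuli)
        assert report.ok, report.violations


class TestDefaultAssignments:
    def test_complementary_partition(self, stimuli, assignments):
        a, b = assignments
        names = {it.picture_name for it in stimuli}
        assert a.ssd250_pictures == b.ssd325_pictures
        assert a.ssd325_pictures == b.ssd250_pictures
        assert a.ssd250_pictures | a.ssd325_pictures == names
        assert len(a.ssd250_pictures) == 20

    def test_deterministic(self, stimuli):
        assert default_assignments(stimuli, 7) == default_assignments(stimuli, 7)


def _toy_stimuli(n=3):
    words = ["aap", "boot", "cent", "duin2", "eik", "fee"]
    return [
        StimulusItem(f"pic{i}", f"cat{i}", f"on{i}", words[i], words[(i + 1) % n])
        for i in range(n)
    ]


class TestRandomizeBlock:
    def test_returns_constraint_satisfying_permutation(self, stimuli, lookup, schedule):
        block = [e for e in schedule if e.block == 1]
        out = randomize_block(block, lookup, seed=7)
        assert sorted(e.picture + e.condition for e in out) == sorted(
            e.picture + e.condition for e in block
        )
        assert [e.position for e in out] == list(range(1, 81))
        # re-validating through the full validator: no adjacency/run violations
        cats = [lookup[e.picture].semantic_category for e in out]
        onsets = [lookup[e.picture].onset_phoneme for e in out]
        assert all(a != b for a, b in zip(cats, cats[1:]))
        assert all(a != b for a, b in zip(onsets, onsets[1:]))

    def test_unsatisfiable_two_same_category(self):
        stims = [
            StimulusItem("pic1", "same", "a", "w1", "w2"),
            StimulusItem("pic2", "same", "b", "w3", "w4"),
        ]
        entries = [_entry("pic1", "related"), _entry("pic2", "unrelated")]
        with pytest.raises(ConstraintError) as exc:
            randomize_block(entries, stims, seed=0, max_attempts=50)
        assert exc.value.attempts == 50

    def test_toy_block_success_probability_by_enumeration(self):
        # independent oracle: enumerate all orders of a 6-trial toy block and
        # confirm valid orders exist, so rejection sampling must terminate
        stims = _toy_stimuli(3)
        entries = [
            _entry(s.picture_name, cond)
            for s in stims
            for cond in ("related", "unrelated")
        ]

        def ok(order):
            for prev, cur in zip(order, order[1:]):
                if prev.picture == cur.picture:  # same category & onset by construction
                    return False
            run = 1
            for prev, cur in zip(order, order[1:]):
                run = run + 1 if prev.condition == cur.condition else 1
                if run > 4:
                    return False
            return True

        n_valid = sum(ok(perm) for perm in itertools.permutations(entries))
        assert n_valid > 0
        out = randomize_block(entries, stims, seed=5, max_attempts=10_000)
        assert ok(out)

    def test_unknown_picture_raises_keyerror(self, lookup):
        with pytest.raises(KeyError, match="ghost"):
            randomize_block([_entry("ghost", "related")], lookup, seed=0)


class TestValidateDesign:
    def test_run_of_five_reported_once_at_position(self, stimuli, lookup, schedule):
        block1 = sorted((e for e in schedule if e.block == 1), key=lambda e: e.position)
        related = [e for e in block1 if e.condition == "related"]
        unrelated = [e for e in block1 if e.condition == "unrelated"]
        # 5 related up front, then double-unrelated/related blocks soaking up the
        # surplus unrelated trials so no other run exceeds the cap
        order = related[:5]
        rest_rel = related[5:]
        rest_unrel = list(unrelated)
        for _ in range(5):
            order += [rest_unrel.pop(), rest_unrel.pop(), rest_rel.pop()]
        while rest_rel:
            order += [rest_unrel.pop(), rest_rel.pop()]
        order += rest_unrel
        assert len(order) == 80
        from dataclasses import replace

        reordered = [replace(e, position=i + 1) for i, e in enumerate(order)]
        rest = [e for e in schedule if e.block != 1]
        report = validate_design(rest + reordered, stimuli)
        runs = [v for v in report.violations if v.kind == "run_length"]
        assert len(runs) == 1
        assert runs[0].block == 1 and runs[0].position == 5

    def test_block_of_79_trials_flags_count_violation(self, stimuli, schedule):
        report = validate_design(schedule[:-1], stimuli)
        assert not report.ok
        assert any(v.kind == "count" for v in report.violations)

    def test_unknown_picture_raises(self, stimuli, schedule):
        from dataclasses import replace

        broken = [replace(schedule[0], picture="ghost")] + list(schedule[1:])
        with pytest.raises(KeyError):
            validate_design(broken, stimuli)

    def test_valid_schedule_report_counts(self, stimuli, schedule):
        report = validate_design(schedule, stimuli)
        assert report.ok
        assert report.n_trials == 320
        assert report.block_counts[2]["go"] == 60
        assert report.block_counts[3]["ssd325"] == 10


class TestPractice:
    def test_practice_block_structure(self):
        practice = build_practice(bundled_practice_stimuli(), seed=3)
        assert len(practice) == 8
        assert all(e.block == 0 for e in practice)
        for cond in ("related", "unrelated"):
            sub = [e for e in practice if e.condition == cond]
            assert len(sub) == 4
            assert sum(e.trial_type == "go" for e in sub) == 3
            assert sum(e.trial_type == "stop" for e in sub) == 1

    def test_practice_excluded_from_validation(self, stimuli, assignments):
        schedule = build_design(stimuli, assignments[0], seed=4, include_practice=True)
        assert len(schedule) == 328
        report = validate_design(schedule, stimuli)
        assert report.ok and report.n_trials == 320


def test_schedule_csv_round_trip(tmp_path, schedule):
    path = tmp_path / "schedule.csv"
    write_schedule(schedule, path)
    assert read_schedule(path) == list(schedule)
    header = path.read_text(encoding="utf-8").splitlines()[0]
    assert header == "participant,block,position,picture,condition,trial_type,ssd_ms"
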