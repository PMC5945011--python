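"""Counterbalanced trial-schedule construction and validation.

The experimental schedule is 320 trials in 4 blocks of 80.  Each block shows
all 40 pictures once with their related and once with their unrelated
distractor (60 go + 20 stop trials; stop trials split 10 related / 10
unrelated and 10 per stop-signal delay).  Across the four blocks every
(picture, condition) combination is a stop trial exactly once, at the SSD
dictated by a between-participant counterbalance assignment that splits the
pictures 20/20 over the two delays.

Block orders are pseudorandomized by rejection sampling: reshuffle until
 - no more than 4 consecutive trials share a distractor condition,
 - no two consecutive target pictures share a semantic category,
 - no two consecutive target pictures share an onset phoneme.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .stimuli import StimulusItem, stimulus_lookup

__all__ = [
    "SSDS_MS",
    "CONDITIONS",
    "ScheduleEntry",
    "CounterbalanceAssignment",
    "ConstraintError",
    "DesignReport",
    "Violation",
    "default_assignments",
    "build_design",
    "build_practice",
    "randomize_block",
    "validate_design",
    "write_schedule",
    "read_schedule",
]

SSDS_MS: tuple[int, int] = (250, 325)
CONDITIONS: tuple[str, str] = ("related", "unrelated")

N_PICTURES = 40
N_BLOCKS = 4
BLOCK_SIZE = 80
STOP_PER_BLOCK = 20
GO_PER_BLOCK = 60
MAX_RUN = 4  # longest allowed run of same-condition trials


class ConstraintError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the ordering constraints."""

    def __init__(self, message: str, attempts: int):
        super().__init__(message)
        self.attempts = attempts


@dataclass(frozen=True)
class ScheduleEntry:
    """One planned trial of the schedule."""

    participant: str
    block: int
    position: int
    picture: str
    condition: str  # "related" | "unrelated"
    trial_type: str  # "go" | "stop"
    ssd_ms: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.trial_type not in ("go", "stop"):
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if (self.ssd_ms is not None) != (self.trial_type == "stop"):
            raise ValueError("ssd_ms must be present iff trial_type is 'stop'")


@dataclass(frozen=True)
class CounterbalanceAssignment:
    """20/20 split of pictures over the two fixed stop-signal delays."""

    ssd250_pictures: frozenset[str]
    ssd325_pictures: frozenset[str]

    def __post_init__(self) -> None:
        if self.ssd250_pictures & self.ssd325_pictures:
            raise ValueError("SSD picture sets must be disjoint")

    def ssd_for(self, picture: str) -> int:
        if picture in self.ssd250_pictures:
            return SSDS_MS[0]
        if picture in self.ssd325_pictures:
            return SSDS_MS[1]
        raise KeyError(f"picture {picture!r} not covered by the assignment")

    def check_partition(self, stimuli: Sequence[StimulusItem]) -> None:
        names = {it.picture_name for it in stimuli}
        union = self.ssd250_pictures | self.ssd325_pictures
        if union != names or len(self.ssd250_pictures) != len(self.ssd325_pictures):
            raise ValueError(
                "assignment must split the stimulus set into two equal disjoint halves"
            )


def default_assignments(
    stimuli: Sequence[StimulusItem], seed: int
) -> tuple[CounterbalanceAssignment, CounterbalanceAssignment]:
    """Two complementary counterbalance assignments derived from a seed.

    Participants are alternated between the two so that each picture serves
    at both delays across the cohort.
    """
    names = sorted(it.picture_name for it in stimuli)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(names))
    half = len(names) // 2
    first = frozenset(names[i] for i in order[:half])
    second = frozenset(names[i] for i in order[half:])
    return (
        CounterbalanceAssignment(first, second),
        CounterbalanceAssignment(second, first),
    )


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _order_ok(
    conditions: np.ndarray, categories: np.ndarray, onsets: np.ndarray, max_run: int = MAX_RUN
) -> bool:
    if categories.size > 1:
        if np.any(categories[1:] == categories[:-1]):
            return False
        if np.any(onsets[1:] == onsets[:-1]):
            return False
    # longest run of equal consecutive condition codes
    if conditions.size > max_run:
        same = conditions[1:] == conditions[:-1]
        run = 1
        for s in same:
            run = run + 1 if s else 1
            if run > max_run:
                return False
    return True


def randomize_block(
    entries: Sequence[ScheduleEntry],
    stimuli: Mapping[str, StimulusItem] | Sequence[StimulusItem],
    seed: int | np.random.Generator,
    max_attempts: int = 10_000,
) -> list[ScheduleEntry]:
    """Reorder a block by rejection sampling until the constraints hold.

    Returns a permutation of ``entries`` with positions renumbered 1..n.
    Raises :class:`ConstraintError` carrying the attempt count when no valid
    order is found within ``max_attempts`` shuffles.
    """
    lookup = stimuli if isinstance(stimuli, Mapping) else stimulus_lookup(stimuli)
    rng = _as_rng(seed)
    n = len(entries)

    try:
        cats = np.array([lookup[e.picture].semantic_category for e in entries])
        onsets = np.array([lookup[e.picture].onset_phoneme for e in entries])
    except KeyError as exc:
        raise KeyError(f"schedule references unknown picture {exc.args[0]!r}") from None
    conds = np.array([0 if e.condition == "related" else 1 for e in entries])

    for attempt in range(1, max_attempts + 1):
        perm = rng.permutation(n)
        if _order_ok(conds[perm], cats[perm], onsets[perm]):
            return [
                replace(entries[j], position=i + 1) for i, j in enumerate(perm)
            ]
    raise ConstraintError(
        f"no constraint-satisfying order found in {max_attempts} attempts", max_attempts
    )


def _stop_cells_per_block(
    assignment: CounterbalanceAssignment, rng: np.random.Generator
) -> list[set[tuple[str, str]]]:
    """Allocate each (picture, condition) pair to the block where it is a stop trial.

    Each block receives 5 pairs from every SSD-set x condition cell, giving
    10 stop trials per SSD and 10 per condition in every block.
    """
    blocks: list[set[tuple[str, str]]] = [set() for _ in range(N_BLOCKS)]
    for pictures in (assignment.ssd250_pictures, assignment.ssd325_pictures):
        for condition in CONDITIONS:
            order = [sorted(pictures)[i] for i in rng.permutation(len(pictures))]
            per_block = len(order) // N_BLOCKS
            for b in range(N_BLOCKS):
                for name in order[b * per_block : (b + 1) * per_block]:
                    blocks[b].add((name, condition))
    return blocks


def build_design(
    stimuli: Sequence[StimulusItem],
    assignment: CounterbalanceAssignment,
    seed: int,
    participant: str = "p01",
    max_attempts: int = 10_000,
    include_practice: bool = False,
    practice_stimuli: Sequence[StimulusItem] | None = None,
) -> list[ScheduleEntry]:
    """Build one participant's full pseudorandomized 320-trial schedule.

    With ``include_practice`` an 8-trial practice block (block 0) built from
    ``practice_stimuli`` is prepended; it is excluded from all analyses.
    """
    if len(stimuli) != N_PICTURES:
        raise ValueError(f"expected {N_PICTURES} stimuli, got {len(stimuli)}")
    names = [it.picture_name for it in stimuli]
    if len(set(names)) != N_PICTURES:
        raise ValueError("duplicate picture names in stimulus set")
    assignment.check_partition(stimuli)

    rng = np.random.default_rng(seed)
    lookup = stimulus_lookup(stimuli)
    stop_cells = _stop_cells_per_block(assignment, rng)

    schedule: list[ScheduleEntry] = []
    if include_practice:
        if practice_stimuli is None:
            from .stimuli import bundled_practice_stimuli

            practice_stimuli = bundled_practice_stimuli()
        schedule.extend(
            build_practice(practice_stimuli, rng, participant=participant, max_attempts=max_attempts)
        )

    for b in range(N_BLOCKS):
        entries = []
        for name in names:
            for condition in CONDITIONS:
                is_stop = (name, condition) in stop_cells[b]
                entries.append(
                    ScheduleEntry(
                        participant=participant,
                        block=b + 1,
                        position=0,
                        picture=name,
                        condition=condition,
                        trial_type="stop" if is_stop else "go",
                        ssd_ms=assignment.ssd_for(name) if is_stop else None,
                    )
                )
        schedule.extend(randomize_block(entries, lookup, rng, max_attempts=max_attempts))
    return schedule


def build_practice(
    practice_stimuli: Sequence[StimulusItem],
    seed: int | np.random.Generator,
    participant: str = "p01",
    max_attempts: int = 10_000,
) -> list[ScheduleEntry]:
    """8 practice trials (block 0): 4 related + 4 unrelated, each with 3 go and 1 stop."""
    if len(practice_stimuli) != 4:
        raise ValueError("practice phase requires exactly 4 pictures")
    rng = _as_rng(seed)
    names = [it.picture_name for it in practice_stimuli]
    entries = []
    for ci, condition in enumerate(CONDITIONS):
        stop_idx = int(rng.integers(4))
        for i, name in enumerate(names):
            is_stop = i == stop_idx
            entries.append(
                ScheduleEntry(
                    participant=participant,
                    block=0,
                    position=0,
                    picture=name,
                    condition=condition,
                    trial_type="stop" if is_stop else "go",
                    ssd_ms=SSDS_MS[ci] if is_stop else None,
                )
            )
    return randomize_block(entries, practice_stimuli, rng, max_attempts=max_attempts)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    kind: str
    block: int | None
    position: int | None
    message: str


@dataclass
class DesignReport:
    n_trials: int
    block_counts: dict[int, dict[str, int]]
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_design(
    schedule: Sequence[ScheduleEntry],
    stimuli: Mapping[str, StimulusItem] | Sequence[StimulusItem],
) -> DesignReport:
    """Check a schedule against the full design contract.

    Returns a report whose violation list is empty iff the schedule is
    conformant.  Practice entries (block 0) are ignored.  Unknown picture
    names raise ``KeyError``.
    """
    lookup = stimuli if isinstance(stimuli, Mapping) else stimulus_lookup(stimuli)
    test = [e for e in schedule if e.block != 0]
    for e in test:
        if e.picture not in lookup:
            raise KeyError(f"schedule references unknown picture {e.picture!r}")

    violations: list[Violation] = []

    def bad(kind: str, block: int | None, position: int | None, message: str) -> None:
        violations.append(Violation(kind, block, position, message))

    if len(test) != N_BLOCKS * BLOCK_SIZE:
        bad("count", None, None, f"expected {N_BLOCKS * BLOCK_SIZE} test trials, got {len(test)}")

    blocks = sorted({e.block for e in test})
    if blocks != list(range(1, N_BLOCKS + 1)):
        bad("count", None, None, f"expected blocks 1..{N_BLOCKS}, got {blocks}")

    block_counts: dict[int, dict[str, int]] = {}
    stop_seen: dict[tuple[str, str], list[int]] = {}

    for b in blocks:
        entries = sorted((e for e in test if e.block == b), key=lambda e: e.position)
        n_go = sum(e.trial_type == "go" for e in entries)
        n_stop = sum(e.trial_type == "stop" for e in entries)
        stop_rel = sum(e.trial_type == "stop" and e.condition == "related" for e in entries)
        stop_unrel = n_stop - stop_rel
        ssd_counts = {d: sum(e.ssd_ms == d for e in entries) for d in SSDS_MS}
        block_counts[b] = {
            "n": len(entries),
            "go": n_go,
            "stop": n_stop,
            "stop_related": stop_rel,
            "stop_unrelated": stop_unrel,
            **{f"ssd{d}": c for d, c in ssd_counts.items()},
        }

        if len(entries) != BLOCK_SIZE:
            bad("count", b, None, f"block {b} has {len(entries)} trials, expected {BLOCK_SIZE}")
        if n_go != GO_PER_BLOCK:
            bad("count", b, None, f"block {b} has {n_go} go trials, expected {GO_PER_BLOCK}")
        if n_stop != STOP_PER_BLOCK:
            bad("count", b, None, f"block {b} has {n_stop} stop trials, expected {STOP_PER_BLOCK}")
        if n_stop == STOP_PER_BLOCK and stop_rel != STOP_PER_BLOCK // 2:
            bad(
                "count",
                b,
                None,
                f"block {b} stop trials split {stop_rel}/{stop_unrel}, expected 10/10",
            )
        for d, c in ssd_counts.items():
            if c != STOP_PER_BLOCK // 2:
                bad("count", b, None, f"block {b} has {c} stop trials at SSD {d}, expected 10")

        cell_counts: dict[tuple[str, str], int] = {}
        for e in entries:
            cell_counts[(e.picture, e.condition)] = cell_counts.get((e.picture, e.condition), 0) + 1
        expected_cells = {(p, c) for p in lookup for c in CONDITIONS}
        if set(cell_counts) != expected_cells or any(v != 1 for v in cell_counts.values()):
            bad(
                "count",
                b,
                None,
                f"block {b} does not contain each picture exactly once per condition",
            )

        for i in range(1, len(entries)):
            prev, cur = entries[i - 1], entries[i]
            p_item, c_item = lookup[prev.picture], lookup[cur.picture]
            if p_item.semantic_category == c_item.semantic_category:
                bad(
                    "adjacency",
                    b,
                    cur.position,
                    f"block {b} pos {cur.position}: consecutive pictures share category "
                    f"{c_item.semantic_category!r}",
                )
            if p_item.onset_phoneme == c_item.onset_phoneme:
                bad(
                    "adjacency",
                    b,
                    cur.position,
                    f"block {b} pos {cur.position}: consecutive pictures share onset "
                    f"{c_item.onset_phoneme!r}",
                )
        run = 1
        for i in range(1, len(entries)):
            run = run + 1 if entries[i].condition == entries[i - 1].condition else 1
            if run == MAX_RUN + 1:  # report once per run, at the first excess trial
                bad(
                    "run_length",
                    b,
                    entries[i].position,
                    f"block {b} pos {entries[i].position}: more than {MAX_RUN} consecutive "
                    f"{entries[i].condition} trials",
                )

        for e in entries:
            if e.trial_type == "stop":
                stop_seen.setdefault((e.picture, e.condition), []).append(e.ssd_ms)

    if len(test) == N_BLOCKS * BLOCK_SIZE and blocks == list(range(1, N_BLOCKS + 1)):
        expected_cells = {(p, c) for p in lookup for c in CONDITIONS}
        if set(stop_seen) != expected_cells or any(len(v) != 1 for v in stop_seen.values()):
            bad("count", None, None, "each picture x condition must be a stop trial exactly once")
        by_pic: dict[str, set[int]] = {}
        for (p, _), ssds in stop_seen.items():
            by_pic.setdefault(p, set()).update(ssds)
        for p, ssds in by_pic.items():
            if len(ssds) > 1:
                bad("count", None, None, f"picture {p!r} appears at multiple SSDs: {sorted(ssds)}")

    return DesignReport(n_trials=len(test), block_counts=block_counts, violations=violations)


# ---------------------------------------------------------------------------
# schedule I/O

_SCHEDULE_HEADER = ["participant", "block", "position", "picture", "condition", "trial_type", "ssd_ms"]


def write_schedule(schedule: Iterable[ScheduleEntry], path: str | Path) -> None:
    """Write a schedule CSV (empty ssd_ms on go trials)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCHEDULE_HEADER)
        for e in schedule:
            writer.writerow(
                [
                    e.participant,
                    e.block,
                    e.position,
                    e.picture,
                    e.condition,
                    e.trial_type,
                    "" if e.ssd_ms is None else e.ssd_ms,
                ]
            )


def read_schedule(path: str | Path) -> list[ScheduleEntry]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return [
            ScheduleEntry(
                participant=row["participant"],
                block=int(row["block"]),
                position=int(row["position"]),
                picture=row["picture"],
                condition=row["condition"],
                trial_type=row["trial_type"],
                ssd_ms=int(row["ssd_ms"]) if row["ssd_ms"] else None,
            )
            for row in reader
        ]
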