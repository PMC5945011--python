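"""Stimulus items for the picture-word-interference stop-signal task.

A stimulus item is a target picture together with a semantically related
distractor word (same category as the picture) and an unrelated distractor
(drawn from a different category).  The bundled 40-item set pairs each
picture with a category-mate distractor and re-uses another item's related
distractor as its unrelated one, so the two conditions share the same word
material.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "StimulusItem",
    "load_stimuli",
    "write_stimuli",
    "bundled_stimuli",
    "bundled_practice_stimuli",
    "stimulus_lookup",
]

_TSV_FIELDS = ("picture", "category", "onset", "related_distractor", "unrelated_distractor")


@dataclass(frozen=True)
class StimulusItem:
    """One target picture with its paired related/unrelated distractor words."""

    picture_name: str
    semantic_category: str
    onset_phoneme: str
    related_distractor: str
    unrelated_distractor: str

    def __post_init__(self) -> None:
        names = {self.picture_name, self.related_distractor, self.unrelated_distractor}
        if len(names) != 3:
            raise ValueError(
                f"picture, related and unrelated distractor must be distinct words: {self}"
            )
        if not self.picture_name or not self.semantic_category or not self.onset_phoneme:
            raise ValueError(f"empty field in stimulus item: {self}")


def load_stimuli(path: str | Path) -> list[StimulusItem]:
    """Read a tab-separated stimulus file.

    Expected header: ``picture  category  onset  related_distractor
    unrelated_distractor`` (UTF-8).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TSV_FIELDS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"stimulus file {path} is missing columns: {sorted(missing)}")
        items = [
            StimulusItem(
                picture_name=row["picture"],
                semantic_category=row["category"],
                onset_phoneme=row["onset"],
                related_distractor=row["related_distractor"],
                unrelated_distractor=row["unrelated_distractor"],
            )
            for row in reader
        ]
    names = [it.picture_name for it in items]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate picture names in {path}")
    return items


def write_stimuli(items: Iterable[StimulusItem], path: str | Path) -> None:
    """Write stimulus items in the same TSV layout accepted by :func:`load_stimuli`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TSV_FIELDS)
        for it in items:
            writer.writerow(
                [
                    it.picture_name,
                    it.semantic_category,
                    it.onset_phoneme,
                    it.related_distractor,
                    it.unrelated_distractor,
                ]
            )


def _load_bundled(name: str) -> list[StimulusItem]:
    ref = resources.files("racestop").joinpath("data", name)
    with resources.as_file(ref) as path:
        return load_stimuli(path)


def bundled_stimuli() -> list[StimulusItem]:
    """The 40-item experimental stimulus set shipped with the package."""
    return _load_bundled("stimuli.tsv")


def bundled_practice_stimuli() -> list[StimulusItem]:
    """The 4 practice pictures (never part of the experimental set)."""
    return _load_bundled("practice_stimuli.tsv")


def stimulus_lookup(items: Iterable[StimulusItem]) -> Mapping[str, StimulusItem]:
    """Index stimuli by picture name."""
    return {it.picture_name: it for it in items}
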