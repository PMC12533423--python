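"""Counterbalanced list construction for the blur x frequency paradigms.

Experiment-1 scheme: a pool of 2N words rotates through the six
(status x blur) cells via a Latin square, producing six lists in which every
(status x blur) cell holds N/3 items and, across the six lists, every word
serves in every cell exactly once.  Experiment-2 scheme: the same rotation is
applied separately within each word-frequency stratum of the non-animal words;
animal words are constant fillers that appear only at study and never at test.

Items are abstract identifiers — no psycholinguistic matching is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "CounterbalanceList",
    "build_counterbalanced_lists",
    "build_exp2_study_list",
    "assign_participants",
    "lists_to_frame",
]

BLUR_LEVELS = ("clear", "low", "high")
STATUSES = ("old", "new")


@dataclass(frozen=True)
class DesignSpec:
    """Sizes and factor levels of one experiment's design."""

    n_words: int = 84                       # per status
    n_nonwords_or_fillers: int = 84
    blur_levels: Sequence[str] = BLUR_LEVELS
    statuses: Sequence[str] = STATUSES
    n_subjects_per_list: int = 36
    frequency_levels: Optional[Sequence[str]] = None

    @property
    def n_lists(self) -> int:
        return len(self.blur_levels) * len(self.statuses)


@dataclass
class CounterbalanceList:
    """One list: item -> (status, blur, frequency) assignment."""

    list_id: int
    assignment: dict = field(default_factory=dict)  # item_id -> (status, blur, freq)

    def items_in_cell(self, status: str, blur: str) -> list:
        return [
            item
            for item, (s, b, _f) in self.assignment.items()
            if s == status and b == blur
        ]


def _latin_rotation(
    item_blocks: list[list], cells: list[tuple], n_lists: int
) -> list[CounterbalanceList]:
    """Rotate item blocks through cells: block b gets cell (b + l) mod n in list l."""
    lists = []
    for l in range(n_lists):
        assignment = {}
        for b, block in enumerate(item_blocks):
            cell = cells[(b + l) % n_lists]
            for item in block:
                assignment[item] = cell
        lists.append(CounterbalanceList(list_id=l + 1, assignment=assignment))
    return lists


def build_counterbalanced_lists(
    spec: DesignSpec, seed: int = 0, items: Optional[Sequence] = None
) -> list[CounterbalanceList]:
    """Experiment-1 style counterbalancing over (status x blur) cells.

    The item pool (size 2 x n_words) is shuffled by ``seed``, cut into
    n_lists equal blocks, and Latin-square rotated so each item occupies every
    cell exactly once across the list set.
    """
    n_cells = spec.n_lists
    pool_size = len(spec.statuses) * spec.n_words
    if items is None:
        items = [f"w{i:03d}" for i in range(pool_size)]
    items = list(items)
    if len(items) != pool_size:
        raise ValueError(f"item pool must have {pool_size} items, got {len(items)}")
    if pool_size % n_cells != 0:
        raise ValueError(
            f"pool of {pool_size} items not divisible over {n_cells} "
            f"(status x blur) cells"
        )
    per_cell = pool_size // n_cells
    if spec.n_words % len(spec.blur_levels) != 0:
        raise ValueError(
            f"{spec.n_words} words per status not divisible over "
            f"{len(spec.blur_levels)} blur levels"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    shuffled = [items[i] for i in order]
    blocks = [shuffled[i * per_cell : (i + 1) * per_cell] for i in range(n_cells)]
    cells = [(s, b, "none") for s in spec.statuses for b in spec.blur_levels]
    return _latin_rotation(blocks, cells, n_cells)


def build_exp2_study_list(
    n_nonanimal_study: int = 90,
    n_animal: int = 45,
    frequency_split: float = 0.5,
    blur_levels: Sequence[str] = BLUR_LEVELS,
    seed: int = 0,
) -> list[CounterbalanceList]:
    """Experiment-2 counterbalancing: blur x frequency non-animal words + animal fillers.

    Non-animal words (pool = 2 x n_nonanimal_study, half per frequency level)
    rotate over the six (status x blur) cells within each frequency stratum.
    Animal fillers are appended to every study list with status 'old' and a
    blur level cycling over the blur set; they never appear at test.
    """
    if frequency_split != 0.5 or n_nonanimal_study % 2 != 0:
        raise ValueError("frequency split must be an even half/half division")
    n_cells = len(blur_levels) * len(STATUSES)
    per_freq_pool = n_nonanimal_study  # pool per frequency level (study + new)
    if per_freq_pool % n_cells != 0:
        raise ValueError(
            f"per-frequency pool {per_freq_pool} not divisible over {n_cells} cells"
        )
    rng = np.random.default_rng(seed)
    lists: list[CounterbalanceList] = [
        CounterbalanceList(list_id=l + 1) for l in range(n_cells)
    ]
    for fi, freq in enumerate(("high", "low")):
        items = [f"n{fi}{i:03d}" for i in range(per_freq_pool)]
        order = rng.permutation(len(items))
        shuffled = [items[i] for i in order]
        per_cell = per_freq_pool // n_cells
        blocks = [shuffled[i * per_cell : (i + 1) * per_cell] for i in range(n_cells)]
        cells = [(s, b, freq) for s in STATUSES for b in blur_levels]
        for l, sub in enumerate(_latin_rotation(blocks, cells, n_cells)):
            lists[l].assignment.update(sub.assignment)
    # constant animal fillers, study-only
    for l in lists:
        for i in range(n_animal):
            blur = blur_levels[i % len(blur_levels)]
            l.assignment[f"a{i:03d}"] = ("old", blur, "none")
    return lists


def assign_participants(
    lists: Sequence[CounterbalanceList], n_per_list: int, seed: int = 0
) -> dict:
    """Allocate exactly n_per_list subjects to each list; returns subject -> list_id."""
    if n_per_list < 1:
        raise ValueError("n_per_list must be >= 1")
    mapping = {}
    k = 0
    for lst in lists:
        for _ in range(n_per_list):
            mapping[f"s{k:04d}"] = lst.list_id
            k += 1
    return mapping


def lists_to_frame(lists: Sequence[CounterbalanceList]) -> pd.DataFrame:
    """Tabular export: one row per (list_id, item_id) with its cell assignment."""
    rows = [
        {
            "list_id": lst.list_id,
            "item_id": item,
            "status": s,
            "blur": b,
            "frequency": f,
        }
        for lst in lists
        for item, (s, b, f) in lst.assignment.items()
    ]
    return pd.DataFrame(rows)


def export_design(lists: Sequence[CounterbalanceList], path: str | Path) -> None:
    lists_to_frame(lists).to_csv(path, index=False)
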