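"""Sensorimotor "word" patterns.

Each word is a pair of sparse binary patterns: a fixed set of cells in the
primary auditory area (A1) and another in the primary articulatory motor area
(M1), activated together during learning.  With the default 17 cells per
25 x 25 area a pattern covers 2.72% of each primary area.  Patterns are drawn
uniformly at random and are shared verbatim between the two members of an
architecture pair.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np


@dataclasses.dataclass(frozen=True)
class WordPattern:
    """Indices (within-area, row-major) of the A1 and M1 cells of one word."""

    a1_cells: tuple[int, ...]
    m1_cells: tuple[int, ...]
    pattern_id: int

    def __post_init__(self):
        if len(set(self.a1_cells)) != len(self.a1_cells):
            raise ValueError("duplicate A1 cells")
        if len(set(self.m1_cells)) != len(self.m1_cells):
            raise ValueError("duplicate M1 cells")


def generate_patterns(
    n_patterns: int,
    cells_per_area: int,
    rng: np.random.Generator,
    area_cells: int = 625,
) -> list[WordPattern]:
    """Draw ``n_patterns`` words, each with ``cells_per_area`` distinct cells
    per primary area, sampled uniformly without replacement within a pattern.
    Different patterns are drawn independently; chance overlap is permitted.
    """
    if cells_per_area > area_cells:
        raise ValueError(
            f"cells_per_area={cells_per_area} exceeds area size {area_cells}"
        )
    out = []
    for pid in range(n_patterns):
        a1 = rng.choice(area_cells, size=cells_per_area, replace=False)
        m1 = rng.choice(area_cells, size=cells_per_area, replace=False)
        out.append(
            WordPattern(tuple(int(i) for i in np.sort(a1)),
                        tuple(int(i) for i in np.sort(m1)), pid)
        )
    return out


def pattern_to_input(
    pattern: WordPattern,
    target_amplitude: float,
    n_areas: int = 6,
    area_cells: int = 625,
    a1_area: int = 0,
    m1_area: int | None = None,
    auditory_only: bool = False,
) -> np.ndarray:
    """External-input vector over all excitatory cells (flat, area-major).

    The full sensorimotor variant drives the pattern's A1 and M1 cells at
    ``target_amplitude``; the auditory-only variant (used in testing) drives
    only the A1 half.
    """
    if m1_area is None:
        m1_area = n_areas - 1
    ext = np.zeros(n_areas * area_cells)
    a1_idx = np.asarray(pattern.a1_cells, dtype=np.int64) + a1_area * area_cells
    ext[a1_idx] = target_amplitude
    if not auditory_only:
        m1_idx = np.asarray(pattern.m1_cells, dtype=np.int64) + m1_area * area_cells
        ext[m1_idx] = target_amplitude
    return ext


def save_patterns(patterns: list[WordPattern], path, meta: dict | None = None) -> None:
    payload = {
        "meta": meta or {},
        "patterns": [
            {"pattern_id": p.pattern_id,
             "a1_cells": list(p.a1_cells),
             "m1_cells": list(p.m1_cells)}
            for p in patterns
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_patterns(path) -> list[WordPattern]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        WordPattern(tuple(d["a1_cells"]), tuple(d["m1_cells"]), d["pattern_id"])
        for d in payload["patterns"]
    ]
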