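"""Project-wide tool class order and Cholec80 occurrence statistics.

The seven-tool class order is fixed everywhere (CSV columns, label vectors,
report rows): grasper, bipolar, hook, scissors, clipper, irrigator,
specimen_bag.

``CHOLEC80_TOOL_COUNTS`` holds the published per-tool occurrence frequencies
of the Cholec80 benchmark (a frame may contain several tools, so the counts
exceed the number of frames).  They drive the default class prevalences of
the synthetic scene generator so that synthetic experiments reproduce the
dataset's severe imbalance: hook and grasper dominate, scissors is rarest.
"""

from __future__ import annotations

import numpy as np

CLASS_NAMES: tuple[str, ...] = (
    "grasper",
    "bipolar",
    "hook",
    "scissors",
    "clipper",
    "irrigator",
    "specimen_bag",
)

N_CLASSES: int = len(CLASS_NAMES)

CHOLEC80_TOOL_COUNTS: dict[str, int] = {
    "grasper": 102_569,
    "bipolar": 8_876,
    "hook": 103_099,
    "scissors": 3_254,
    "clipper": 5_986,
    "irrigator": 9_814,
    "specimen_bag": 11_462,
}


def cholec80_total_count() -> int:
    """Total tool occurrences across all classes."""
    return sum(CHOLEC80_TOOL_COUNTS.values())


def default_prevalences() -> np.ndarray:
    """Per-class presence probabilities proportional to the Cholec80 counts.

    Counts are normalized by their grand total, so the values sum to 1 and a
    synthetic frame carries one tool on average, with the same rank order of
    rarity as the real dataset.
    """
    counts = np.array([CHOLEC80_TOOL_COUNTS[c] for c in CLASS_NAMES], dtype=float)
    return counts / counts.sum()
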