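"""Bayes-factor tests of listener-culture differences per condition cell.

For each (dimension, emotion, speaker culture) triple the two listener
cultures' cell means are compared: the likelihood is a normal centred on
the mean difference with the pooled standard error (root sum of squares
of the two cell s.e.'s, independent groups) as sd, and — since no
direction is predicted for culture differences — the prior is the
symmetric standard normal.  BF > 3 supports a difference, BF < 1/3
supports no difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .bayes import Grid, SUPPORT_EFFECT, SUPPORT_NULL, analyze
from .preprocessing import CELL_KEYS

SUPPORT_DIFFERENCE = "support_difference"
SUPPORT_NO_DIFFERENCE = "support_no_difference"

_CATEGORY_MAP = {
    SUPPORT_EFFECT: SUPPORT_DIFFERENCE,
    SUPPORT_NULL: SUPPORT_NO_DIFFERENCE,
    "inconclusive": "inconclusive",
}

COMPARE_KEYS = ["dimension", "emotion", "speaker_culture"]


@dataclass
class CultureComparison:
    dimension: str
    emotion: str
    speaker_culture: str
    mean_diff: float
    pooled_se: float
    bf: float
    ci_lo: float
    ci_hi: float
    category: str


def compare_cultures(cell_a, cell_b, grid: Grid | None = None, level: float = 0.95) -> CultureComparison:
    """Compare two cell estimates that differ only in listener culture.

    The difference is oriented as ``cell_a - cell_b``; with the symmetric
    prior the Bayes factor is invariant to the orientation.
    """
    for key in COMPARE_KEYS:
        if getattr(cell_a, key) != getattr(cell_b, key):
            raise ValueError(f"cells differ in {key}; cannot compare")
    if cell_a.listener_culture == cell_b.listener_culture:
        raise ValueError("cells must come from different listener cultures")
    diff = float(cell_a.mean - cell_b.mean)
    pooled_se = float(np.hypot(cell_a.se, cell_b.se))
    res = analyze(diff, pooled_se, "none", grid, level)
    return CultureComparison(
        dimension=cell_a.dimension,
        emotion=cell_a.emotion,
        speaker_culture=cell_a.speaker_culture,
        mean_diff=diff,
        pooled_se=pooled_se,
        bf=res.bf,
        ci_lo=res.ci_lo,
        ci_hi=res.ci_hi,
        category=_CATEGORY_MAP[res.category],
    )


def compare_all(
    cells: pd.DataFrame, grid: Grid | None = None, level: float = 0.95
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """One listener-culture comparison per (dimension, emotion, speaker culture).

    The difference is oriented first-minus-second in sorted listener-
    culture order (australia - india for the default labels).  Returns
    the comparison table and the category counts.
    """
    cultures = sorted(cells["listener_culture"].unique())
    if len(cultures) != 2:
        raise ValueError(f"expected exactly 2 listener cultures, got {cultures}")
    wide = cells.set_index(CELL_KEYS).sort_index()

    rows = []
    triples = cells[COMPARE_KEYS].drop_duplicates().sort_values(COMPARE_KEYS)
    for rec in triples.itertuples(index=False):
        try:
            a = wide.loc[(rec.dimension, rec.emotion, rec.speaker_culture, cultures[0])]
            b = wide.loc[(rec.dimension, rec.emotion, rec.speaker_culture, cultures[1])]
        except KeyError as err:
            raise ValueError(
                f"incomplete cell table at {(rec.dimension, rec.emotion, rec.speaker_culture)}"
            ) from err
        def as_cell(row, culture):
            return SimpleNamespace(
                dimension=rec.dimension,
                emotion=rec.emotion,
                speaker_culture=rec.speaker_culture,
                listener_culture=culture,
                mean=float(row["mean"]),
                se=float(row["se"]),
            )

        comp = compare_cultures(as_cell(a, cultures[0]), as_cell(b, cultures[1]), grid, level)
        rows.append(vars(comp))
    results = pd.DataFrame(rows)
    counts = {
        SUPPORT_DIFFERENCE: int((results["category"] == SUPPORT_DIFFERENCE).sum()),
        SUPPORT_NO_DIFFERENCE: int((results["category"] == SUPPORT_NO_DIFFERENCE).sum()),
        "inconclusive": int((results["category"] == "inconclusive").sum()),
    }
    return results, counts
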