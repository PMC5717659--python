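"""Theory-based directional predictions and their evaluation over cells.

Appraisal theory predicts, for many (appraisal dimension, emotion) pairs,
whether listeners should rate the dimension high or low — e.g. high
novelty for anger, low urgency for serenity.  The built-in table encodes
36 such directional predictions over 6 dimensions x 8 emotions; pairs
without a literature-based prediction get the symmetric prior.  Each of
the 192 condition cells is analyzed with the matching prior, and the
per-cell evidence categories are tallied into the study's bookkeeping:
supported / null / inconclusive counts, the in-group vs out-group
breakdown, and a Beta posterior for the joint accuracy of the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Tuple

import pandas as pd

from .bayes import Grid, SUPPORT_EFFECT, SUPPORT_NULL, analyze
from .preprocessing import CELL_KEYS
from .synthetic import DIMENSIONS, EMOTIONS

#: Directional predictions: high = rated above the listener's own average,
#: low = below.  Pairs not listed carry no prediction.
DEFAULT_PREDICTIONS: Dict[Tuple[str, str], str] = {}
for _dim, _high, _low in [
    ("novelty", ("anger", "fear", "happiness"), ("sadness", "serenity")),
    ("pleasantness", ("happiness", "pride", "relief", "serenity"), ("anger", "fear", "sadness", "shame")),
    ("goal_conduciveness", ("happiness", "pride", "relief"), ("anger", "fear", "sadness", "shame")),
    ("urgency", ("anger", "fear"), ("happiness", "relief", "sadness", "serenity")),
    ("power", ("anger", "happiness", "pride"), ("fear", "sadness", "shame")),
    ("norm_compatibility", ("happiness", "pride"), ("anger", "shame")),
]:
    for _e in _high:
        DEFAULT_PREDICTIONS[(_dim, _e)] = "high"
    for _e in _low:
        DEFAULT_PREDICTIONS[(_dim, _e)] = "low"


class PredictionTable:
    """Mapping (dimension, emotion) -> direction, defaulting to "none"."""

    def __init__(self, directions: Mapping[Tuple[str, str], str]):
        for (dim, emo), d in directions.items():
            if d not in ("high", "low", "none"):
                raise ValueError(f"invalid direction {d!r} for ({dim}, {emo})")
        self._directions = {k: v for k, v in directions.items() if v != "none"}

    def direction(self, dimension: str, emotion: str) -> str:
        return self._directions.get((dimension, emotion), "none")

    @property
    def n_directional(self) -> int:
        return len(self._directions)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"dimension": d, "emotion": e, "direction": v}
            for (d, e), v in sorted(self._directions.items())
        ]
        return pd.DataFrame(rows, columns=["dimension", "emotion", "direction"])


def load_prediction_table(
    source: str | Path | Mapping[Tuple[str, str], str] | None = None,
    dimensions: tuple = DIMENSIONS,
    emotions: tuple = EMOTIONS,
) -> PredictionTable:
    """Built-in table (source=None), a mapping, or a CSV with columns
    dimension, emotion, direction.  Labels are validated against the
    given dimension and emotion vocabularies."""
    if source is None:
        mapping = dict(DEFAULT_PREDICTIONS)
    elif isinstance(source, (str, Path)):
        df = pd.read_csv(source)
        required = {"dimension", "emotion", "direction"}
        if not required.issubset(df.columns):
            raise ValueError(f"prediction CSV must have columns {sorted(required)}")
        mapping = {
            (r.dimension, r.emotion): r.direction for r in df.itertuples(index=False)
        }
    else:
        mapping = dict(source)
    for dim, emo in mapping:
        if dim not in dimensions:
            raise ValueError(f"unknown dimension {dim!r}")
        if emo not in emotions:
            raise ValueError(f"unknown emotion {emo!r}")
    return PredictionTable(mapping)


def accuracy_posterior(
    n_supported: int, n_not_supported: int, literal: bool = False
) -> Tuple[float, float]:
    """Beta posterior (alpha, beta) for the joint accuracy of predictions.

    Default is the Beta-binomial posterior under a uniform prior:
    alpha = supported + 1, beta = not-supported + 1, so the posterior mean
    is (s+1)/(s+f+2).  ``literal=True`` instead uses the total prediction
    count + 1 as alpha, an alternative bookkeeping in which alpha counts
    all predictions rather than only the supported ones.
    """
    if n_supported < 0 or n_not_supported < 0:
        raise ValueError("counts must be non-negative")
    if literal:
        return (n_supported + n_not_supported + 1.0, n_not_supported + 1.0)
    return (n_supported + 1.0, n_not_supported + 1.0)


@dataclass
class EvaluationSummary:
    """Tallies over the predicted cells plus the accuracy posterior."""

    n_predicted_cells: int
    n_support_effect: int
    n_support_null: int
    n_inconclusive: int
    by_condition: Dict[Tuple[str, str], Dict[str, int]] = field(default_factory=dict)
    accuracy_alpha: float = 1.0
    accuracy_beta: float = 1.0

    def __post_init__(self) -> None:
        total = self.n_support_effect + self.n_support_null + self.n_inconclusive
        if total != self.n_predicted_cells:
            raise ValueError("category counts must sum to the predicted-cell count")

    @property
    def accuracy_mean(self) -> float:
        return self.accuracy_alpha / (self.accuracy_alpha + self.accuracy_beta)


def evaluate_cells(
    cells: pd.DataFrame,
    table: PredictionTable | None = None,
    grid: Grid | None = None,
    level: float = 0.95,
    literal_beta: bool = False,
) -> Tuple[pd.DataFrame, EvaluationSummary]:
    """Bayes analysis of every condition cell with its matching prior.

    Cells whose (dimension, emotion) has a directional prediction get the
    half-normal prior in that direction and count toward the summary;
    the rest get the symmetric prior and are reported but not tallied.
    In-group means the listener culture equals the speaker culture.
    """
    table = table or load_prediction_table()
    grid = grid or Grid()
    required = set(CELL_KEYS + ["mean", "se"])
    if not required.issubset(cells.columns):
        raise ValueError(f"cell table must have columns {sorted(required)}")
    expected = pd.MultiIndex.from_product(
        [sorted(cells[k].unique()) for k in CELL_KEYS], names=CELL_KEYS
    )
    missing = expected.difference(pd.MultiIndex.from_frame(cells[CELL_KEYS]))
    if len(missing):
        raise ValueError(f"missing cells: {list(missing)[:10]}")

    rows = []
    for rec in cells.itertuples(index=False):
        direction = table.direction(rec.dimension, rec.emotion)
        res = analyze(rec.mean, rec.se, direction, grid, level)
        rows.append(
            {
                "dimension": rec.dimension,
                "emotion": rec.emotion,
                "speaker_culture": rec.speaker_culture,
                "listener_culture": rec.listener_culture,
                "prior_type": direction,
                "mean": rec.mean,
                "se": rec.se,
                "bf": res.bf,
                "ci_lo": res.ci_lo,
                "ci_hi": res.ci_hi,
                "category": res.category,
            }
        )
    results = pd.DataFrame(rows)

    predicted = results[results["prior_type"] != "none"]
    counts = predicted["category"].value_counts()
    n_sup = int(counts.get(SUPPORT_EFFECT, 0))
    n_null = int(counts.get(SUPPORT_NULL, 0))
    n_inc = len(predicted) - n_sup - n_null
    by_condition: Dict[Tuple[str, str], Dict[str, int]] = {}
    for rec in predicted.itertuples(index=False):
        group = "in-group" if rec.listener_culture == rec.speaker_culture else "out-group"
        key = (rec.listener_culture, group)
        by_condition.setdefault(key, {}).setdefault(rec.category, 0)
        by_condition[key][rec.category] += 1
    alpha, beta = accuracy_posterior(n_sup, len(predicted) - n_sup, literal=literal_beta)
    summary = EvaluationSummary(
        n_predicted_cells=len(predicted),
        n_support_effect=n_sup,
        n_support_null=n_null,
        n_inconclusive=n_inc,
        by_condition=by_condition,
        accuracy_alpha=alpha,
        accuracy_beta=beta,
    )
    return results, summary
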