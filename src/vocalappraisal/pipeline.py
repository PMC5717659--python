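"""End-to-end orchestration: simulate -> preprocess -> evaluate -> compare
-> reliability -> acoustics, driven by one configuration object.

Every stage draws randomness from its own stream derived from a master
seed, so rerunning a single stage in isolation reproduces its output
from the full run.  All tabular outputs are CSV; the headline counts go
into a JSON summary.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import acoustics, culture, predictions, preprocessing, reliability
from .bayes import Grid
from .synthetic import (
    AcousticTruth,
    StudyDesign,
    TruthProfile,
    apply_missingness,
    generate_acoustics,
    generate_ratings,
    generate_stimuli,
)

log = logging.getLogger("vocalappraisal")


@dataclass
class RunConfig:
    """Settings for a full synthetic-study run."""

    outdir: Path = Path("results")
    seed: int = 0
    grid_step: float = 0.001
    n_splits: int = 10_000
    effect: float = 0.8
    culture_offsets: Mapping[tuple, float] = field(default_factory=dict)
    missing_mode: Mapping[str, str] = field(
        default_factory=lambda: {"australia": "partial", "india": "complete"}
    )
    n_listeners: Mapping[str, int] = field(
        default_factory=lambda: {"australia": 80, "india": 40}
    )
    with_acoustics: bool = True
    selected_cues: list[str] | None = None
    ratings_csv: Path | None = None  # real data instead of the generator
    features_csv: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        if "outdir" in raw:
            raw["outdir"] = Path(raw["outdir"])
        for key in ("ratings_csv", "features_csv"):
            if raw.get(key):
                raw[key] = Path(raw[key])
        offsets = raw.pop("culture_offsets", None)
        cfg = cls(**raw)
        if offsets:
            cfg.culture_offsets = {
                (o["dimension"], o["emotion"], o["listener_culture"]): o["offset"]
                for o in offsets
            }
        return cfg

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage sub-seed below 2**31 (process-independent)."""
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % (2**31))


def simulate(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Generate ratings (with per-culture missingness) and acoustics."""
    design = StudyDesign(n_listeners=dict(config.n_listeners), seed=config.stage_seed("simulate"))
    truth = TruthProfile.from_directions(
        predictions.DEFAULT_PREDICTIONS,
        effect=config.effect,
        culture_offset=dict(config.culture_offsets),
    )
    stimuli = generate_stimuli(design, truth)
    ratings = generate_ratings(design, truth)
    parts = []
    for lc, mode in config.missing_mode.items():
        sub = ratings[ratings["listener_culture"] == lc]
        parts.append(
            apply_missingness(sub, mode=mode, seed=config.stage_seed(f"missing:{lc}"))
        )
    ratings = pd.concat(parts, ignore_index=True)
    out = {"ratings": ratings, "stimuli": stimuli}
    if config.with_acoustics:
        out["features"] = generate_acoustics(
            design, AcousticTruth(), seed=config.stage_seed("acoustics"), stimuli=stimuli
        )
    return out


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run every stage and write CSV/JSON outputs under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = Grid(step=config.grid_step)

    if config.ratings_csv is not None:
        ratings = pd.read_csv(config.ratings_csv)
        stimuli = ratings[
            ["stimulus_id", "emotion", "speaker_culture", "speaker_id"]
        ].drop_duplicates()
        features = pd.read_csv(config.features_csv) if config.features_csv else None
    else:
        data = simulate(config)
        ratings, stimuli = data["ratings"], data["stimuli"]
        features = data.get("features")
        ratings.to_csv(outdir / "ratings.csv", index=False)
        if features is not None:
            features.to_csv(outdir / "acoustic_features.csv", index=False)
    log.info("ratings: %d records, %d stimuli", len(ratings), stimuli["stimulus_id"].nunique())

    kept = preprocessing.filter_complete_coverage(ratings)
    z = preprocessing.zscore_by_participant_dimension(kept)
    cells = preprocessing.cell_estimates(preprocessing.participant_cell_means(z, stimuli))
    cells.to_csv(outdir / "cell_estimates.csv", index=False)
    log.info("aggregated %d condition cells", len(cells))

    cell_results, summary = predictions.evaluate_cells(cells, grid=grid)
    cell_results.to_csv(outdir / "cell_bayes.csv", index=False)

    comparisons, comparison_counts = culture.compare_all(cells, grid=grid)
    comparisons.to_csv(outdir / "culture_comparisons.csv", index=False)

    rel = reliability.reliability_table(
        z, n_splits=config.n_splits, seed=config.stage_seed("reliability")
    )
    rel.to_csv(outdir / "reliability.csv", index=False)

    corr_table = None
    if features is not None:
        zfeat = acoustics.zscore_by_speaker(features)
        n_factors = acoustics.parallel_analysis(
            zfeat, seed=config.stage_seed("parallel")
        )
        solution = acoustics.pca_varimax(zfeat, max(n_factors, 1))
        solution.rotated_loadings.to_csv(outdir / "factor_loadings.csv")
        selected = config.selected_cues or list(solution.rotated_loadings.abs().idxmax())
        stim_means = acoustics.stimulus_mean_ratings(z)
        corr_table = acoustics.correlate_cues(stim_means, zfeat, selected, stimuli)
        corr_table.to_csv(outdir / "cue_correlations.csv", index=False)
        log.info("parallel analysis retained %d factor(s)", n_factors)
    else:
        n_factors = None
        log.info("no acoustic table; acoustic stage skipped")

    result = {
        "seed": config.seed,
        "grid_step": config.grid_step,
        "n_stimuli": int(stimuli["stimulus_id"].nunique()),
        "n_cells": int(len(cells)),
        "n_predicted_cells": summary.n_predicted_cells,
        "n_support_effect": summary.n_support_effect,
        "n_support_null": summary.n_support_null,
        "n_inconclusive": summary.n_inconclusive,
        "accuracy_posterior": {
            "alpha": summary.accuracy_alpha,
            "beta": summary.accuracy_beta,
            "mean": summary.accuracy_mean,
        },
        "by_condition": {
            f"{lc}/{grp}": counts for (lc, grp), counts in summary.by_condition.items()
        },
        "n_comparisons": int(len(comparisons)),
        "comparison_counts": comparison_counts,
        "reliability": {
            f"{r.rater_culture}/{r.dimension}": round(r.spearman_brown, 4)
            for r in rel.itertuples(index=False)
        },
        "retained_factors": n_factors,
    }
    (outdir / "summary.json").write_text(json.dumps(result, indent=2))
    return result
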