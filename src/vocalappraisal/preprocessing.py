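"""Within-participant standardization and aggregation to condition cells.

Raw 1-5 ratings are z-transformed per (participant, dimension) across all
of that participant's rated stimuli — both speaker cultures pooled — which
removes idiosyncratic response bias and scale use.  The z ratings are then
averaged per participant within each (dimension, emotion, speaker culture)
cell, and finally summarized across participants of the same listener
culture into the cell means and standard errors that feed the Bayesian
stage: dimensions x emotions x 2 speaker cultures x 2 listener cultures
cells (192 in the default design).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

CELL_KEYS = ["dimension", "emotion", "speaker_culture", "listener_culture"]


def filter_complete_coverage(ratings: pd.DataFrame) -> pd.DataFrame:
    """Drop participants who miss any (emotion, speaker culture) cell.

    Mirrors the exclusion rule of incomplete-design studies: a participant
    must have rated at least one stimulus from every emotion category of
    both speaker cultures to contribute to every cell.
    """
    full = (
        ratings[["emotion", "speaker_culture"]].drop_duplicates().shape[0]
    )
    coverage = ratings.groupby("participant_id").apply(
        lambda g: g[["emotion", "speaker_culture"]].drop_duplicates().shape[0],
        include_groups=False,
    )
    dropped = coverage.index[coverage < full]
    if len(dropped):
        warnings.warn(
            f"excluding {len(dropped)} participant(s) without full emotion x "
            f"speaker-culture coverage: {sorted(dropped)[:5]}...",
            stacklevel=2,
        )
    return ratings[~ratings["participant_id"].isin(dropped)].reset_index(drop=True)


def zscore_by_participant_dimension(ratings: pd.DataFrame) -> pd.DataFrame:
    """z-transform the value column within each (participant, dimension).

    Uses the n-1 sample standard deviation.  Groups with zero variance
    (or a single rating) carry no ordering information; their z values are
    set to 0 and a warning lists the groups, rather than dropping the
    participant.
    """
    out = ratings.copy()
    grouped = out.groupby(["participant_id", "dimension"])["value"]
    mean = grouped.transform("mean")
    sd = grouped.transform("std")  # ddof=1; NaN for singleton groups
    degenerate = (sd == 0) | sd.isna()
    if degenerate.any():
        bad = out.loc[degenerate, ["participant_id", "dimension"]].drop_duplicates()
        warnings.warn(
            f"{len(bad)} constant (participant, dimension) group(s) mapped to z=0: "
            f"{list(bad.itertuples(index=False, name=None))[:5]}",
            stacklevel=2,
        )
    z = (out["value"] - mean) / sd
    out["value"] = z.where(~degenerate, 0.0)
    return out


def participant_cell_means(
    z_ratings: pd.DataFrame, stimuli: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-participant mean z rating in each (dimension, emotion, speaker culture) cell.

    Cells a participant never rated are absent from the output, not zero.
    When a stimulus metadata table is supplied, every rated stimulus_id
    must appear in it.
    """
    if stimuli is not None:
        known = set(stimuli["stimulus_id"])
        orphans = set(z_ratings["stimulus_id"]) - known
        if orphans:
            raise ValueError(f"rated stimuli missing from metadata: {sorted(orphans)[:10]}")
    means = (
        z_ratings.groupby(
            ["participant_id", "listener_culture", "dimension", "emotion", "speaker_culture"],
            sort=True,
        )["value"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "participant_mean", "size": "n_stimuli"})
    )
    return means


def cell_estimates(participant_means: pd.DataFrame) -> pd.DataFrame:
    """Across-participant mean, s.e. and n for every condition cell.

    se is the n-1 sample sd of participant means divided by sqrt(n).
    Errors if any expected cell (full cross of observed labels) is absent
    or has fewer than 2 contributing participants.
    """
    agg = (
        participant_means.groupby(CELL_KEYS, sort=True)["participant_mean"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"count": "n"})
    )
    agg["se"] = agg["std"] / np.sqrt(agg["n"])
    agg = agg.drop(columns=["std"])

    expected = pd.MultiIndex.from_product(
        [sorted(participant_means[k].unique()) for k in CELL_KEYS], names=CELL_KEYS
    )
    got = pd.MultiIndex.from_frame(agg[CELL_KEYS])
    missing = expected.difference(got)
    if len(missing):
        raise ValueError(f"missing condition cells: {list(missing)[:10]}")
    thin = agg[agg["n"] < 2]
    if len(thin):
        raise ValueError(
            "cells with fewer than 2 participants: "
            f"{list(thin[CELL_KEYS].itertuples(index=False, name=None))[:10]}"
        )
    return agg[CELL_KEYS + ["mean", "se", "n"]]


def preprocess(ratings: pd.DataFrame) -> pd.DataFrame:
    """Full chain: coverage filter -> z-transform -> cell estimates."""
    kept = filter_complete_coverage(ratings)
    z = zscore_by_participant_dimension(kept)
    return cell_estimates(participant_cell_means(z))
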