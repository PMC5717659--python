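"""Synthetic raters, stimuli and acoustic cue tables with known ground truth.

The generator emulates a balanced two-culture listening study: speakers
from two cultures each contribute 8 stimuli for each of 8 enacted
emotions (128 stimuli in total), and listeners from the same two cultures
rate every stimulus on six appraisal dimensions using a 1-5 scale.

Ratings follow an ordered-threshold (cumulative) model: a latent
continuous judgement is the sum of a (dimension, emotion) cell effect, an
optional listener-culture offset, a stimulus-specific deviation, a
participant response bias, and participant-scaled residual noise; four
fixed cutpoints discretize the latent value onto the 1-5 scale.  The
participant bias/scale terms create exactly the kind of idiosyncratic
scale use that per-participant z-transformation is meant to remove.

Acoustic tables follow a linear factor model: each cue is a loading-
weighted sum of per-emotion factor scores plus a per-speaker baseline and
noise, so per-speaker standardization, parallel analysis and varimax
recovery are all exercised non-trivially.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Literal, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import hadamard

EMOTIONS = (
    "anger",
    "fear",
    "happiness",
    "pride",
    "relief",
    "sadness",
    "serenity",
    "shame",
)
DIMENSIONS = (
    "novelty",
    "pleasantness",
    "goal_conduciveness",
    "urgency",
    "power",
    "norm_compatibility",
)
CULTURES = ("australia", "india")

#: Columns of the long-format rating table.
RATING_COLUMNS = (
    "participant_id",
    "listener_culture",
    "stimulus_id",
    "emotion",
    "speaker_culture",
    "speaker_id",
    "dimension",
    "value",
)

#: Per-participant stimulus retention probability for the partial design.
#: 0.643 * 128 stimuli reproduces the study-scale average of ~82 rated
#: stimuli per participant under the incomplete (Australian-style) design.
DEFAULT_RETENTION = 0.643


class ConfigurationError(ValueError):
    """Invalid generator configuration (labels, counts, cutpoints)."""


def _check_labels(name: str, labels: Sequence[str]) -> None:
    if len(labels) == 0:
        raise ConfigurationError(f"{name} must be non-empty")
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"{name} contains duplicates: {list(labels)}")


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the emulated study.

    Defaults mirror the study scale: 8 emotions x 8 stimuli per speaker
    culture (128 stimuli), 6 appraisal dimensions, 80 listeners in the
    incomplete-design culture and 40 in the complete-design culture.
    """

    emotions: Tuple[str, ...] = EMOTIONS
    dimensions: Tuple[str, ...] = DIMENSIONS
    speaker_cultures: Tuple[str, str] = CULTURES
    listener_cultures: Tuple[str, str] = CULTURES
    stimuli_per_emotion_per_culture: int = 8
    n_listeners: Mapping[str, int] = field(
        default_factory=lambda: {"australia": 80, "india": 40}
    )
    n_speakers_per_culture: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        _check_labels("emotions", self.emotions)
        _check_labels("dimensions", self.dimensions)
        _check_labels("speaker_cultures", self.speaker_cultures)
        _check_labels("listener_cultures", self.listener_cultures)
        if self.stimuli_per_emotion_per_culture < 1:
            raise ConfigurationError("stimuli_per_emotion_per_culture must be >= 1")
        if self.n_speakers_per_culture < 1:
            raise ConfigurationError("n_speakers_per_culture must be >= 1")
        for culture in self.listener_cultures:
            if self.n_listeners.get(culture, 0) < 1:
                raise ConfigurationError(f"n_listeners missing or < 1 for {culture!r}")

    @property
    def n_stimuli(self) -> int:
        return (
            len(self.emotions)
            * len(self.speaker_cultures)
            * self.stimuli_per_emotion_per_culture
        )


@dataclass(frozen=True)
class TruthProfile:
    """Latent generating parameters for the rating model (z units).

    ``cell_effect`` maps (dimension, emotion) to the latent mean;
    ``culture_offset`` maps (dimension, emotion, listener_culture) to an
    additive shift.  Unlisted keys default to 0.
    """

    cell_effect: Mapping[Tuple[str, str], float] = field(default_factory=dict)
    culture_offset: Mapping[Tuple[str, str, str], float] = field(default_factory=dict)
    participant_bias_sd: float = 0.3
    participant_scale_sd: float = 0.2
    residual_sd: float = 1.0
    #: Optional per-stimulus latent deviation.  0 by default: condition
    #: cells then have no shared stimulus-sampling error, so cell means are
    #: unbiased under the null.  Set > 0 to give stimuli individual
    #: appraisal profiles (needed to link acoustic cues to ratings).
    stimulus_effect_sd: float = 0.0
    discretization_cutpoints: Tuple[float, float, float, float] = (-1.2, -0.4, 0.4, 1.2)

    def __post_init__(self) -> None:
        cp = self.discretization_cutpoints
        if len(cp) != 4 or not all(a < b for a, b in zip(cp, cp[1:])):
            raise ConfigurationError(f"cutpoints must be 4 strictly increasing reals, got {cp}")
        for name in ("participant_bias_sd", "participant_scale_sd", "stimulus_effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.residual_sd <= 0:
            raise ConfigurationError("residual_sd must be > 0")

    @classmethod
    def from_directions(
        cls,
        directions: Mapping[Tuple[str, str], str],
        effect: float = 0.8,
        **kwargs,
    ) -> "TruthProfile":
        """Cell effects of +-``effect`` following a direction table.

        ``directions`` maps (dimension, emotion) to "high"/"low"/"none";
        "none" entries contribute a 0 effect.
        """
        cell = {
            key: (effect if d == "high" else -effect)
            for key, d in directions.items()
            if d in ("high", "low")
        }
        return cls(cell_effect=cell, **kwargs)


@dataclass(frozen=True)
class AcousticTruth:
    """Linear factor model behind the synthetic acoustic cue table."""

    n_cues: int = 88
    n_factors: int = 9
    loadings: np.ndarray | None = None  # cue x factor; default built per seed
    factor_by_emotion: Mapping[str, np.ndarray] | None = None
    cue_noise_sd: float = 0.5
    speaker_baseline_sd: float = 1.0
    #: Optional direct links cue -> (dimension, coefficient): the cue gains
    #: ``coefficient`` times the stimulus's latent appraisal value, tying
    #: acoustic structure to the rating model's ground truth.
    appraisal_links: Mapping[str, Tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_factors > self.n_cues:
            raise ConfigurationError("n_factors must not exceed n_cues")
        if self.cue_noise_sd <= 0:
            raise ConfigurationError("cue_noise_sd must be > 0")
        if self.loadings is not None:
            L = np.asarray(self.loadings, float)
            if L.shape != (self.n_cues, self.n_factors) or not np.all(np.isfinite(L)):
                raise ConfigurationError("loadings must be a finite n_cues x n_factors matrix")

    def resolved_loadings(self, rng: np.random.Generator) -> np.ndarray:
        """Default structure: each cue loads 0.8 on one factor, round-robin."""
        if self.loadings is not None:
            return np.asarray(self.loadings, float)
        L = np.zeros((self.n_cues, self.n_factors))
        L[np.arange(self.n_cues), np.arange(self.n_cues) % self.n_factors] = 0.8
        return L

    def resolved_factor_scores(
        self, emotions: Sequence[str], rng: np.random.Generator
    ) -> Dict[str, np.ndarray]:
        if self.factor_by_emotion is not None:
            return {e: np.asarray(self.factor_by_emotion[e], float) for e in emotions}
        return {e: rng.standard_normal(self.n_factors) for e in emotions}


def orthogonal_factor_scores(
    emotions: Sequence[str], n_factors: int
) -> Dict[str, np.ndarray]:
    """Exactly orthogonal unit-variance factor scores across emotions.

    Uses +-1 columns of a Hadamard matrix (skipping the constant column),
    so the factors are mutually orthogonal and mean-centred over the
    emotion set — the cleanest possible input for factor-recovery checks.
    Requires a power-of-two emotion count >= n_factors + 1.
    """
    n = len(emotions)
    if n & (n - 1):
        raise ConfigurationError("orthogonal scores need a power-of-two emotion count")
    if n_factors > n - 1:
        raise ConfigurationError(f"at most {n - 1} orthogonal factors for {n} emotions")
    H = hadamard(n).astype(float)
    return {e: H[i, 1 : n_factors + 1] for i, e in enumerate(emotions)}


def directional_culture_offsets(
    directions: Mapping[Tuple[str, str], str],
    dimension: str,
    magnitude: float,
    listener_culture: str,
) -> Dict[Tuple[str, str, str], float]:
    """Culture offsets that amplify one dimension's predicted pattern.

    For every emotion with a directional prediction on ``dimension``, the
    given listener culture's latent judgement is shifted by ``magnitude``
    in the predicted direction.  Because the shift varies across emotions
    (and averages out over the dimension), it survives the per-participant
    z-transform, unlike a uniform shift of the whole dimension.
    """
    out: Dict[Tuple[str, str, str], float] = {}
    for (dim, emo), d in directions.items():
        if dim == dimension and d in ("high", "low"):
            out[(dim, emo, listener_culture)] = magnitude if d == "high" else -magnitude
    return out


def cue_names(n_cues: int) -> list[str]:
    return [f"cue_{i:02d}" for i in range(n_cues)]


def generate_stimuli(design: StudyDesign, truth: TruthProfile) -> pd.DataFrame:
    """Stimulus metadata plus latent per-dimension appraisal deviations.

    Deterministic given ``design.seed``; :func:`generate_ratings` derives
    its stimulus table from this function so the two always agree.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    rows = []
    for culture in design.speaker_cultures:
        speakers = [f"{culture[:3]}_spk{i:02d}" for i in range(design.n_speakers_per_culture)]
        culture_rows = [
            {
                "stimulus_id": f"{culture[:3]}_{emotion}_{i:02d}",
                "emotion": emotion,
                "speaker_culture": culture,
            }
            for emotion in design.emotions
            for i in range(design.stimuli_per_emotion_per_culture)
        ]
        # each speaker portrays a random mix of emotions (cycled over a
        # shuffled stimulus order, so speaker stimulus counts differ by
        # at most one and never align with the emotion blocks)
        order = rng.permutation(len(culture_rows))
        for j, idx in enumerate(order):
            culture_rows[idx]["speaker_id"] = speakers[j % len(speakers)]
        rows.extend(culture_rows)
    stimuli = pd.DataFrame(rows)[["stimulus_id", "emotion", "speaker_culture", "speaker_id"]]
    jitter = rng.normal(0.0, truth.stimulus_effect_sd, size=(len(stimuli), len(design.dimensions)))
    for j, dim in enumerate(design.dimensions):
        stimuli[f"latent_{dim}"] = jitter[:, j]
    return stimuli


def generate_ratings(design: StudyDesign, truth: TruthProfile) -> pd.DataFrame:
    """Complete-design rating table: every listener rates every stimulus.

    latent = cell_effect + culture_offset + stimulus deviation
             + participant bias + participant scale * noise
    and the 1-5 rating is ``1 + #cutpoints below latent``.
    """
    stimuli = generate_stimuli(design, truth)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 2]))
    dims = list(design.dimensions)
    n_stim = len(stimuli)

    cell = np.array(
        [
            [truth.cell_effect.get((d, e), 0.0) for e in stimuli["emotion"]]
            for d in dims
        ]
    )  # dim x stimulus
    stim_dev = stimuli[[f"latent_{d}" for d in dims]].to_numpy().T  # dim x stimulus
    cutpoints = np.asarray(truth.discretization_cutpoints)

    frames = []
    for culture in design.listener_cultures:
        n_p = design.n_listeners[culture]
        bias = rng.normal(0.0, truth.participant_bias_sd, size=n_p)
        scale = rng.lognormal(0.0, truth.participant_scale_sd, size=n_p) if truth.participant_scale_sd > 0 else np.ones(n_p)
        offset = np.array(
            [
                [truth.culture_offset.get((d, e, culture), 0.0) for e in stimuli["emotion"]]
                for d in dims
            ]
        )
        noise = rng.normal(0.0, truth.residual_sd, size=(n_p, len(dims), n_stim))
        latent = (
            (cell + offset + stim_dev)[None, :, :]
            + bias[:, None, None]
            + scale[:, None, None] * noise
        )
        values = 1 + np.searchsorted(cutpoints, latent.ravel()).reshape(latent.shape)

        pid = np.array([f"{culture[:3]}_p{i:03d}" for i in range(n_p)])
        frame = pd.DataFrame(
            {
                "participant_id": np.repeat(pid, len(dims) * n_stim),
                "listener_culture": culture,
                "stimulus_id": np.tile(np.repeat(stimuli["stimulus_id"].to_numpy(), 1), n_p * len(dims)),
                "emotion": np.tile(stimuli["emotion"].to_numpy(), n_p * len(dims)),
                "speaker_culture": np.tile(stimuli["speaker_culture"].to_numpy(), n_p * len(dims)),
                "speaker_id": np.tile(stimuli["speaker_id"].to_numpy(), n_p * len(dims)),
                "dimension": np.tile(np.repeat(dims, n_stim), n_p),
                "value": values.ravel().astype(int),
            }
        )
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out[list(RATING_COLUMNS)]


def apply_missingness(
    ratings: pd.DataFrame,
    mode: Literal["complete", "partial"] = "partial",
    min_per_emotion: int = 1,
    seed: int = 0,
    retention: float = DEFAULT_RETENTION,
) -> pd.DataFrame:
    """Thin each participant's stimulus set (partial) or return as-is.

    Partial mode keeps each stimulus with probability ``retention`` and
    then repairs every (participant, emotion, speaker culture) group that
    fell below ``min_per_emotion`` by restoring randomly chosen dropped
    stimuli, mimicking an incomplete design in which every participant
    still covers every emotion from both speaker cultures.
    """
    if mode == "complete":
        return ratings.copy()
    if mode != "partial":
        raise ValueError(f"unknown mode {mode!r}")
    if min_per_emotion < 1:
        raise ValueError("min_per_emotion must be >= 1")
    if not 0 < retention <= 1:
        raise ValueError("retention must be in (0, 1]")

    stim_meta = (
        ratings[["stimulus_id", "emotion", "speaker_culture"]]
        .drop_duplicates()
        .set_index("stimulus_id")
    )
    group_sizes = stim_meta.groupby(["emotion", "speaker_culture"]).size()
    if (group_sizes < min_per_emotion).any():
        bad = group_sizes[group_sizes < min_per_emotion]
        raise ValueError(f"min_per_emotion={min_per_emotion} unsatisfiable for groups {list(bad.index)}")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    stim_ids = stim_meta.index.to_numpy()
    groups = {
        key: idx.to_numpy()
        for key, idx in stim_meta.groupby(["emotion", "speaker_culture"]).groups.items()
    }

    kept_pairs = []
    for pid in ratings["participant_id"].unique():
        keep = set(stim_ids[rng.random(len(stim_ids)) < retention])
        for key, members in groups.items():
            have = [s for s in members if s in keep]
            deficit = min_per_emotion - len(have)
            if deficit > 0:
                dropped = np.array([s for s in members if s not in keep])
                keep.update(rng.choice(dropped, size=deficit, replace=False))
        kept_pairs.extend((pid, s) for s in keep)

    kept = pd.MultiIndex.from_tuples(kept_pairs, names=["participant_id", "stimulus_id"])
    idx = pd.MultiIndex.from_frame(ratings[["participant_id", "stimulus_id"]])
    return ratings[idx.isin(kept)].reset_index(drop=True)


def generate_acoustics(
    design: StudyDesign,
    acoustic_truth: AcousticTruth,
    seed: int = 0,
    stimuli: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Raw stimulus-by-cue table from the linear factor model.

    Per-speaker baselines are injected so that per-speaker z-scoring is a
    real operation, not a no-op.  When ``stimuli`` (from
    :func:`generate_stimuli`) is given, its latent appraisal columns feed
    any configured ``appraisal_links``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    if stimuli is None:
        stimuli = generate_stimuli(design, TruthProfile())
    L = acoustic_truth.resolved_loadings(rng)
    scores = acoustic_truth.resolved_factor_scores(design.emotions, rng)
    names = cue_names(acoustic_truth.n_cues)

    speakers = stimuli["speaker_id"].unique()
    baseline = {
        spk: rng.normal(0.0, acoustic_truth.speaker_baseline_sd, size=acoustic_truth.n_cues)
        for spk in speakers
    }

    F = np.stack([scores[e] for e in stimuli["emotion"]])  # stimulus x factor
    X = F @ L.T
    X += np.stack([baseline[s] for s in stimuli["speaker_id"]])
    X += rng.normal(0.0, acoustic_truth.cue_noise_sd, size=X.shape)

    for cue, (dim, coef) in acoustic_truth.appraisal_links.items():
        col = f"latent_{dim}"
        if col not in stimuli.columns:
            raise ConfigurationError(f"appraisal link {cue!r} refers to unknown dimension {dim!r}")
        X[:, names.index(cue)] += coef * stimuli[col].to_numpy()

    out = stimuli[["stimulus_id", "speaker_id"]].copy()
    for j, name in enumerate(names):
        out[name] = X[:, j]
    return out
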