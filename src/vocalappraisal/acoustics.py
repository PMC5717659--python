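"""Acoustic-cue standardization, factor reduction and rating correlations.

Acoustic cue tables (one row per stimulus, one column per cue, e.g. the
88 extended-GeMAPS descriptors) are first z-scored within speaker to
remove baseline differences between voices.  Horn's parallel analysis
against random-data eigenvalue envelopes decides how many principal
components to retain, and a Kaiser-normalized varimax rotation of the
retained PCA loadings yields an interpretable factor solution.  Finally,
per-stimulus mean ratings of each appraisal dimension are correlated
(Pearson) with selected cues, separately per listener and speaker
culture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ID_COLUMNS = ["stimulus_id", "speaker_id"]


def _cue_columns(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns if c not in ID_COLUMNS]


def zscore_by_speaker(features: pd.DataFrame) -> pd.DataFrame:
    """z-transform every cue within speaker (n-1 sd).

    A speaker with a single stimulus has no within-speaker variance to
    standardize against and raises; a cue that is constant within a
    speaker maps to 0 with a warning.
    """
    counts = features.groupby("speaker_id").size()
    singletons = counts.index[counts < 2]
    if len(singletons):
        raise ValueError(f"speaker(s) with < 2 stimuli: {sorted(singletons)}")
    out = features.copy()
    cues = _cue_columns(features)
    grouped = out.groupby("speaker_id")[cues]
    mean = grouped.transform("mean")
    sd = grouped.transform("std")
    degenerate = sd == 0
    if degenerate.any().any():
        bad_cues = degenerate.any(axis=0)
        warnings.warn(
            f"constant within-speaker cue group(s) mapped to z=0 in cues: "
            f"{list(bad_cues.index[bad_cues])[:5]}",
            stacklevel=2,
        )
    z = (out[cues] - mean) / sd
    out[cues] = z.where(~degenerate, 0.0)
    return out


def parallel_analysis(
    z_features: pd.DataFrame,
    n_iterations: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
) -> int:
    """Horn's parallel analysis on the cue correlation matrix.

    Retains the leading components whose observed eigenvalue exceeds the
    ``quantile`` envelope of eigenvalues from ``n_iterations`` random
    standard-normal datasets of the same shape; stops at the first
    component that fails.
    """
    X = z_features[_cue_columns(z_features)].to_numpy()
    n, p = X.shape
    if n <= 1 or p < 1:
        raise ValueError("need at least 2 stimuli and 1 cue")
    corr = np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise ValueError("degenerate correlation matrix (zero-variance cue?)")
    obs = np.sort(np.linalg.eigvalsh(corr))[::-1]

    rng = np.random.default_rng(seed)
    rand = np.empty((n_iterations, p))
    for i in range(n_iterations):
        Z = rng.standard_normal((n, p))
        rand[i] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    envelope = np.quantile(rand, quantile, axis=0)

    retained = 0
    for lam, env in zip(obs, envelope):
        if lam > env:
            retained += 1
        else:
            break
    return retained


def varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Varimax rotation (SVD formulation), optionally Kaiser-normalized."""
    L = np.asarray(loadings, float).copy()
    p, k = L.shape
    if k < 2:
        return L
    comm = np.sqrt((L**2).sum(axis=1))
    if normalize:
        nonzero = comm > 0
        L[nonzero] /= comm[nonzero, None]
    T = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ T
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        T = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    L = L @ T
    if normalize:
        L[nonzero] *= comm[nonzero, None]
    return L


@dataclass
class FactorSolution:
    eigenvalues: np.ndarray
    retained_factor_count: int
    rotated_loadings: pd.DataFrame
    random_eigenvalue_envelope: np.ndarray | None = field(default=None, repr=False)


def pca_varimax(z_features: pd.DataFrame, n_factors: int) -> FactorSolution:
    """PCA on the cue correlation matrix + varimax of the leading loadings.

    Factors are ordered by rotated sum of squared loadings; each factor's
    sign is fixed so its largest-magnitude loading is positive.
    """
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    cues = _cue_columns(z_features)
    X = z_features[cues].to_numpy()
    corr = np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise ValueError("degenerate correlation matrix")
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    rank = int((eigval > 1e-10).sum())
    if n_factors > rank:
        raise ValueError(f"n_factors={n_factors} exceeds matrix rank {rank}")
    L = eigvec[:, :n_factors] * np.sqrt(eigval[:n_factors])
    Lr = varimax(L) if n_factors > 1 else L.copy()

    ss = (Lr**2).sum(axis=0)
    Lr = Lr[:, np.argsort(ss)[::-1]]
    for j in range(Lr.shape[1]):
        i = int(np.argmax(np.abs(Lr[:, j])))
        if Lr[i, j] < 0:
            Lr[:, j] *= -1
    return FactorSolution(
        eigenvalues=eigval,
        retained_factor_count=n_factors,
        rotated_loadings=pd.DataFrame(
            Lr, index=cues, columns=[f"factor_{j + 1}" for j in range(n_factors)]
        ),
    )


def stimulus_mean_ratings(z_ratings: pd.DataFrame) -> pd.DataFrame:
    """Mean z rating per (stimulus, dimension, listener culture).

    Every stimulus must be covered by at least one listener from each
    culture.
    """
    means = (
        z_ratings.groupby(["stimulus_id", "dimension", "listener_culture"], sort=True)[
            "value"
        ]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mean_rating", "size": "n_listeners"})
    )
    cultures = z_ratings["listener_culture"].unique()
    dims = z_ratings["dimension"].unique()
    expected_per_stim = len(cultures) * len(dims)
    per_stim = means.groupby("stimulus_id").size()
    uncovered = per_stim.index[per_stim < expected_per_stim]
    if len(uncovered):
        raise ValueError(f"stimuli without full listener-culture coverage: {sorted(uncovered)[:10]}")
    return means


def correlate_cues(
    stimulus_means: pd.DataFrame,
    z_features: pd.DataFrame,
    selected_cues: list[str],
    stimulus_cultures: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r between mean ratings and cue values per culture pair.

    Correlations run over stimuli within each speaker culture separately
    (64 per culture in the default design), for every combination of
    selected cue, appraisal dimension and listener culture.  A zero-
    variance series yields NaN, not 0.
    """
    missing = [c for c in selected_cues if c not in z_features.columns]
    if missing:
        raise ValueError(f"selected cues absent from feature table: {missing}")
    meta = stimulus_cultures[["stimulus_id", "speaker_culture"]].drop_duplicates()
    feats = z_features.merge(meta, on="stimulus_id", validate="one_to_one")

    rows = []
    for speaker_culture, fsub in feats.groupby("speaker_culture"):
        fsub = fsub.set_index("stimulus_id")
        msub = stimulus_means[stimulus_means["stimulus_id"].isin(fsub.index)]
        for (dim, lc), grp in msub.groupby(["dimension", "listener_culture"]):
            ratings = grp.set_index("stimulus_id")["mean_rating"].reindex(fsub.index)
            for cue in selected_cues:
                x = fsub[cue].to_numpy()
                y = ratings.to_numpy()
                if np.std(x) == 0 or np.std(y) == 0 or len(x) < 2:
                    r = np.nan
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                rows.append(
                    {
                        "cue": cue,
                        "dimension": dim,
                        "listener_culture": lc,
                        "speaker_culture": speaker_culture,
                        "r": r,
                        "n": len(x),
                    }
                )
    return pd.DataFrame(rows)
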