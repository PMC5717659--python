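"""Inter-rater consistency per (appraisal dimension, rater culture).

The primary measure is the randomized split-half correlation: raters are
repeatedly split into halves, each half's per-stimulus mean profile is
computed, the two profiles are correlated (Pearson, over stimuli covered
by both halves), and the mean correlation across splits is stepped up to
the full panel with the Spearman-Brown prophecy formula R = 2r/(1+r).
This works for incomplete designs, where classical intraclass
correlations are unavailable.  For complete designs, ICC for two-way
average measures (consistency form, (MS_stimuli - MS_error)/MS_stimuli)
serves as a cross-check; on well-behaved complete data the two measures
agree closely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ReliabilityResult:
    dimension: str
    rater_culture: str
    n_splits: int
    mean_split_r: float
    spearman_brown: float
    seed: int
    icc2k: float | None = None
    n_resampled: int = 0


def spearman_brown(r: float) -> float:
    """Step a half-panel correlation up to the full panel: 2r / (1 + r)."""
    if r <= -1:
        raise ValueError("Spearman-Brown undefined for r <= -1")
    return 2 * r / (1 + r)


def _rating_matrix(ratings: pd.DataFrame, dimension: str, culture: str) -> pd.DataFrame:
    sub = ratings[
        (ratings["dimension"] == dimension) & (ratings["listener_culture"] == culture)
    ]
    if sub.empty:
        raise ValueError(f"no ratings for dimension={dimension!r}, culture={culture!r}")
    return sub.pivot_table(
        index="participant_id", columns="stimulus_id", values="value", aggfunc="mean"
    )


def _split_correlations(R: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    """Pearson r between half-profiles for each split (rows of mask1).

    Stimuli covered by only one half are excluded pairwise; splits with
    fewer than 2 common stimuli or a zero-variance profile come back NaN.
    """
    obs = np.isfinite(R)
    R0 = np.where(obs, R, 0.0)
    m1 = mask1.astype(float)
    m2 = 1.0 - m1
    with np.errstate(invalid="ignore", divide="ignore"):
        c1 = m1 @ obs
        c2 = m2 @ obs
        mean1 = (m1 @ R0) / c1
        mean2 = (m2 @ R0) / c2
        valid = (c1 > 0) & (c2 > 0)
        x = np.where(valid, mean1, np.nan)
        y = np.where(valid, mean2, np.nan)
        nv = valid.sum(axis=1)
        mx = np.nansum(x, axis=1) / nv
        my = np.nansum(y, axis=1) / nv
        xc = np.where(valid, x - mx[:, None], 0.0)
        yc = np.where(valid, y - my[:, None], 0.0)
        num = (xc * yc).sum(axis=1)
        den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        r = num / den
    r[nv < 2] = np.nan
    return r


def split_half(
    ratings: pd.DataFrame,
    dimension: str,
    culture: str,
    n_splits: int = 10_000,
    seed: int = 0,
) -> ReliabilityResult:
    """Randomized split-half reliability with Spearman-Brown correction.

    Splits partition the raters into halves of size floor(n/2) and
    ceil(n/2).  Splits that produce an undefined correlation (fewer than
    2 stimuli covered by both halves, or a constant profile) are
    discarded and redrawn; the count is reported.  The correction is
    applied to the mean of the split correlations.
    """
    M = _rating_matrix(ratings, dimension, culture)
    n_raters = M.shape[0]
    if n_raters < 4:
        raise ValueError(f"need >= 4 raters, got {n_raters}")
    R = M.to_numpy()
    rng = np.random.default_rng(seed)

    def draw(k: int) -> np.ndarray:
        u = rng.random((k, n_raters))
        ranks = u.argsort(axis=1).argsort(axis=1)
        return ranks < n_raters // 2

    rs = _split_correlations(R, draw(n_splits))
    n_resampled = 0
    attempts = 0
    while np.isnan(rs).any() and attempts < 100:
        bad = np.isnan(rs)
        n_resampled += int(bad.sum())
        rs[bad] = _split_correlations(R, draw(int(bad.sum())))
        attempts += 1
    rs = rs[np.isfinite(rs)]
    if rs.size == 0:
        raise ValueError("no valid split produced a defined correlation")
    if n_resampled:
        warnings.warn(f"{n_resampled} degenerate split(s) redrawn", stacklevel=2)
    mean_r = float(rs.mean())
    return ReliabilityResult(
        dimension=dimension,
        rater_culture=culture,
        n_splits=n_splits,
        mean_split_r=mean_r,
        spearman_brown=spearman_brown(mean_r),
        seed=seed,
        n_resampled=n_resampled,
    )


def icc2k(ratings: pd.DataFrame, dimension: str, culture: str) -> float:
    """Two-way average-measures intraclass correlation, consistency form.

    Stimuli are targets, raters are judges.  Requires a complete design
    (every rater rated every stimulus); incomplete designs raise, since
    the mean-squares decomposition is undefined with missing cells.
    """
    M = _rating_matrix(ratings, dimension, culture)
    if M.isna().any().any():
        raise ValueError(
            f"incomplete design for dimension={dimension!r}, culture={culture!r}: "
            "ICC requires every rater to rate every stimulus"
        )
    X = M.to_numpy().T  # stimuli x raters
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 stimuli and >= 2 raters")
    grand = X.mean()
    ss_rows = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((X - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows == 0:
        raise ValueError("no between-stimulus variance; ICC undefined")
    return float((ms_rows - ms_err) / ms_rows)


def reliability_table(
    ratings: pd.DataFrame,
    n_splits: int = 10_000,
    seed: int = 0,
    with_icc: bool = True,
) -> pd.DataFrame:
    """Split-half (and, where the design is complete, ICC) per
    (dimension, rater culture)."""
    rows = []
    for culture in sorted(ratings["listener_culture"].unique()):
        for dim in sorted(ratings["dimension"].unique()):
            res = split_half(ratings, dim, culture, n_splits=n_splits, seed=seed)
            if with_icc:
                try:
                    res.icc2k = icc2k(ratings, dim, culture)
                except ValueError:
                    res.icc2k = None
            rows.append(vars(res))
    return pd.DataFrame(rows)
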