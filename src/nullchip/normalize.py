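"""Within-array and between-array normalization, and probe scores.

The probe score is the replicate-mean normalized log2(ChIP/input) ratio
with negative means assigned zero; on this scale a score of s corresponds
to 2^s-fold enrichment of ChIP over total input DNA (score 1 = 2-fold).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

log = logging.getLogger(__name__)

#: additive intensity floor applied before taking logs; the raw-intensity
#: processing of the original two-colour arrays is not recoverable, so this
#: is an explicit deviation knob rather than a reconstruction
INTENSITY_FLOOR = 0.5

#: locally weighted regression defaults (tricube weights are lowess's own)
LOESS_SPAN = 0.3
LOESS_ITERATIONS = 2


def fold_enrichment(score) -> np.ndarray | float:
    """Map a probe/window score to its fold-enrichment: fold(s) = 2**s."""
    return np.power(2.0, score)


def normalize_within_array(chip: np.ndarray, reference: np.ndarray, *,
                           span: float = LOESS_SPAN, iterations: int = LOESS_ITERATIONS,
                           center: bool = True) -> np.ndarray:
    """Remove intensity-dependent bias from one two-channel array.

    Computes M = log2(chip/reference) and A = mean log2 intensity, fits a
    locally weighted regression of M on A and subtracts the fitted trend.
    Non-positive intensities are floored at INTENSITY_FLOOR (logged). With
    fewer than 20 probes the local fit is unstable and the array is
    median-centered instead (with a warning). `center=False` keeps a flat
    trend's constant offset instead of removing it.
    """
    chip = np.asarray(chip, dtype=float)
    reference = np.asarray(reference, dtype=float)
    n_floored = int((chip < INTENSITY_FLOOR).sum() + (reference < INTENSITY_FLOOR).sum())
    if n_floored:
        log.info("floored %d non-positive intensities at %.2f", n_floored, INTENSITY_FLOOR)
    chip = np.maximum(chip, INTENSITY_FLOOR)
    reference = np.maximum(reference, INTENSITY_FLOOR)

    m = np.log2(chip) - np.log2(reference)
    a = 0.5 * (np.log2(chip) + np.log2(reference))

    if len(m) < 20:
        warnings.warn("fewer than 20 probes: falling back to median-centering",
                      stacklevel=2)
        return m - (np.median(m) if center else 0.0)

    if np.ptp(a) < 1e-8:
        # no intensity spread: the only removable trend is the constant
        trend = np.full_like(m, np.median(m))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            trend = lowess(m, a, frac=span, it=iterations, xvals=a)
        if not np.all(np.isfinite(trend)):
            trend = np.full_like(m, np.median(m))
    if not center:
        trend = trend - trend.mean()
    return m - trend


def quantile_normalize(arrays: pd.DataFrame) -> pd.DataFrame:
    """Force every array (column) onto the common per-rank mean distribution.

    After normalization each column's sorted values equal the per-rank mean
    of the input columns' sorted values; within-column ranks are preserved
    and ties receive the average of their tied ranks' target values.
    """
    if arrays.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    x = arrays.to_numpy(dtype=float)
    n = x.shape[0]
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    positions = np.arange(1, n + 1, dtype=float)
    from scipy.stats import rankdata
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, target)
    return pd.DataFrame(out, index=arrays.index, columns=arrays.columns)


def compute_probe_scores(replicates: pd.DataFrame) -> pd.Series:
    """Replicate-mean log-ratio per probe, clipped at zero.

    Missing values are averaged over the available replicates (and the probe
    flagged in the log) rather than dropping the probe, which would punch
    holes in the window lattice.
    """
    if replicates.shape[1] < 1:
        raise ValueError("need at least one replicate")
    n_missing = int(replicates.isna().any(axis=1).sum())
    if n_missing:
        log.warning("%d probe(s) had missing replicate values; mean taken over "
                    "available replicates", n_missing)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean = replicates.mean(axis=1, skipna=True)
    scores = mean.clip(lower=0.0).fillna(0.0)
    scores.name = "probe_score"
    return scores


def genotype_probe_scores(replicates: pd.DataFrame, *,
                          skip_quantile: bool = False) -> pd.Series:
    """Quantile-normalize one genotype's replicate log-ratios, then average.

    Arrays of each genotype are normalized separately; replicate averaging
    happens after between-array normalization.
    """
    if not skip_quantile and replicates.shape[1] >= 2:
        replicates = quantile_normalize(replicates)
    return compute_probe_scores(replicates)
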