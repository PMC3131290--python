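"""Expression preprocessing and litter-aware differential expression.

Pipeline: per-array background correction against negative-control means,
a variance-stabilizing generalized-log transform, a detection filter
(detected in at least one sample), correlation-based outlier QC, then a
per-gene least-squares fit of value ~ genotype + litter with an optional
empirical-Bayes variance-moderation step, Benjamini-Hochberg FDR, and a
litter-restricted genotype-label permutation test.

Litter is modelled as a fixed blocking factor: embryos from one pregnancy
share environment and genetic background, and the permutation scheme below
only exchanges genotype labels within the genotype counts of each litter,
so the permutation null respects the same blocking as the model.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma


class DesignMatrixError(ValueError):
    pass


@dataclass
class ExpressionStudy:
    """Gene x sample matrix with genotype/litter metadata.

    expr: transformed-scale values, genes in rows, samples in columns.
    meta: indexed by sample, columns 'genotype' ('wt'|'mut') and 'litter'.
    detection: per-(gene, sample) detection score in [0, 1].
    """

    expr: pd.DataFrame
    meta: pd.DataFrame
    detection: pd.DataFrame | None = None
    qc_flags: pd.Series | None = None

    def __post_init__(self) -> None:
        if not set(self.expr.columns) <= set(self.meta.index):
            raise ValueError("metadata does not cover every sample column")
        if self.detection is not None and self.detection.shape != self.expr.shape:
            raise ValueError("detection matrix incongruent with expression matrix")
        self.meta = self.meta.loc[self.expr.columns]

    def subset_samples(self, keep) -> "ExpressionStudy":
        keep = list(keep)
        return ExpressionStudy(
            expr=self.expr[keep].copy(),
            meta=self.meta.loc[keep].copy(),
            detection=None if self.detection is None else self.detection[keep].copy(),
            qc_flags=self.qc_flags,
        )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def background_correct(raw: pd.DataFrame, control_means: pd.Series) -> pd.DataFrame:
    """Subtract each array's mean negative-control signal from its column."""
    missing = [c for c in raw.columns if c not in control_means.index]
    if missing:
        raise ValueError(f"no negative-control summary for array(s) {missing}")
    return raw.sub(control_means[raw.columns], axis=1)


def glog2(x, c):
    """Generalized log: log2((x + sqrt(x^2 + c^2)) / 2).

    Monotone in x, ~log2(x) for x >> c, linear near 0, defined for
    negative background-corrected values; glog2(0) = log2(c/2).
    """
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + c * c)) / 2.0)


def vst(corrected: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing transform of a background-corrected matrix.

    Each array is first put on a common scale by a robustly fitted factor
    (median absolute deviation matched to the across-array geometric mean),
    then glog-transformed with a per-array c taken as the robust spread of
    the array's low-intensity values — the regime where additive noise
    dominates and the transform must stay linear.
    """
    x = corrected.to_numpy(dtype=float)
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med[None, :]), axis=0) * 1.4826
    if np.any(mad <= 0):
        j = int(np.argmax(mad <= 0))
        raise ValueError(f"array {corrected.columns[j]!r} has no spread; "
                         "calibration is degenerate")
    ref = float(np.exp(np.mean(np.log(mad))))
    scaled = x * (ref / mad)[None, :]

    out = np.empty_like(scaled)
    for j in range(scaled.shape[1]):
        col = scaled[:, j]
        low = col[col <= np.quantile(col, 0.25)]
        c = max(1.4826 * np.median(np.abs(low - np.median(low))), 1e-8)
        out[:, j] = glog2(col, c)
    return pd.DataFrame(out, index=corrected.index, columns=corrected.columns)


def detection_filter(study: ExpressionStudy, min_score: float = 0.95) -> ExpressionStudy:
    """Keep genes detected (score >= min_score) in at least one sample."""
    if study.detection is None:
        raise ValueError("detection matrix required")
    keep = (study.detection >= min_score).any(axis=1)
    return ExpressionStudy(expr=study.expr.loc[keep].copy(), meta=study.meta,
                           detection=study.detection.loc[keep].copy(),
                           qc_flags=study.qc_flags)


def qc_outliers(study: ExpressionStudy, n_mads: float = 3.0) -> pd.Series:
    """Flag samples whose median inter-sample correlation collapses.

    A sample is flagged when its median Pearson correlation with the other
    samples lies strictly more than `n_mads` robust deviations (scaled MAD)
    below the cohort median. Errors out if more than 25% of samples would
    be flagged — that indicates a batch problem, not individual outliers.
    """
    if study.expr.shape[1] < 4:
        raise ValueError("outlier QC needs at least 4 samples")
    corr = np.corrcoef(study.expr.to_numpy(dtype=float).T)
    np.fill_diagonal(corr, np.nan)
    med_corr = np.nanmedian(corr, axis=1)
    center = np.median(med_corr)
    mad = 1.4826 * np.median(np.abs(med_corr - center))
    cutoff = center - n_mads * mad
    flags = pd.Series(med_corr < cutoff, index=study.expr.columns, name="qc_outlier")
    if flags.mean() > 0.25:
        raise ValueError(
            f"{int(flags.sum())}/{len(flags)} samples flagged as outliers; "
            f"median correlations: {np.round(med_corr, 3).tolist()}")
    return flags


# ---------------------------------------------------------------------------
# the linear model
# ---------------------------------------------------------------------------

def _design_matrix(meta: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    genotype = (meta["genotype"] == "mut").to_numpy(dtype=float)
    litters = pd.Categorical(meta["litter"])
    cols = [np.ones(len(meta)), genotype]
    names = ["intercept", "genotype"]
    for lev in litters.categories[1:]:
        cols.append((litters == lev).astype(float))
        names.append(f"litter[{lev}]")
    X = np.column_stack(cols)
    base = np.column_stack([c for c, n in zip(cols, names) if n != "genotype"])
    if np.linalg.matrix_rank(X) <= np.linalg.matrix_rank(base):
        raise DesignMatrixError(
            "genotype is confounded with litter (constant within every litter)")
    return X, names


def _moment_match_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0^2 for variance moderation.

    Moment matching on z = log(s2): under s2 ~ s0^2 * chi2_df/df scaled by a
    gene variance with inverse-chi2(d0) prior, E[z] and Var[z] involve
    digamma/trigamma terms; Var[z] - trigamma(df/2) = trigamma(d0/2) is
    inverted by Newton iteration. Returns (inf, exp-mean) when the observed
    spread of log-variances is no larger than the chi2 sampling noise.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    target = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if target <= 0:
        return math.inf, float(np.exp(e_mean))
    y = 0.5 + 2.0 / target  # limma's starting value for d0/2
    for _ in range(50):
        tri = float(polygamma(1, y))
        delta = tri * (1.0 - tri / target) / float(polygamma(2, y))
        y = max(y + delta, 1e-8)
        if abs(delta) < 1e-10:
            break
    d0 = 2.0 * y
    s02 = float(np.exp(e_mean + digamma(y) - math.log(y)))
    return d0, s02


def fit_de(study: ExpressionStudy, moderate: bool = True,
           include_litter: bool = True) -> pd.DataFrame:
    """Per-gene genotype contrast from a genotype + litter linear model.

    Ordinary least squares per gene (vectorized across genes); the genotype
    effect is mutant minus wild-type on the transformed (log2-like) scale.
    With `moderate=True` the residual variances are shrunk towards a pooled
    prior estimated by moment matching across genes before forming the
    t-statistic (degrees of freedom increase by the prior df) — the small-n
    stabilization microarray studies rely on. Both the moderated and the
    ordinary p-value are reported.
    """
    meta = study.meta
    counts = meta["genotype"].value_counts()
    if counts.get("wt", 0) < 2 or counts.get("mut", 0) < 2:
        raise ValueError("need at least 2 samples per genotype")
    if include_litter and meta["litter"].nunique() > 1:
        X, names = _design_matrix(meta)
    else:
        genotype = (meta["genotype"] == "mut").to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(meta)), genotype])
        names = ["intercept", "genotype"]

    Y = study.expr.to_numpy(dtype=float).T  # samples x genes
    n, p = X.shape
    df = n - p
    if df < 1:
        raise DesignMatrixError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    s2 = rss / df
    g = names.index("genotype")
    effect = beta[g]
    c_gg = xtx_inv[g, g]

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2 * c_gg)
        t_ord = effect / se
    p_ord = 2.0 * stats.t.sf(np.abs(t_ord), df)
    p_ord = np.where(np.isfinite(t_ord), p_ord, 0.0)

    if moderate:
        d0, s02 = _moment_match_prior(s2, df)
        if math.isinf(d0):
            s2_post = np.full_like(s2, s02)
            df_post: float = np.inf
        else:
            s2_post = (d0 * s02 + df * s2) / (d0 + df)
            df_post = d0 + df
        with np.errstate(divide="ignore", invalid="ignore"):
            t_mod = effect / np.sqrt(s2_post * c_gg)
        if math.isinf(df_post):
            p_mod = 2.0 * stats.norm.sf(np.abs(t_mod))
        else:
            p_mod = 2.0 * stats.t.sf(np.abs(t_mod), df_post)
        p_mod = np.where(np.isfinite(t_mod), p_mod, 0.0)
        t_use, p_use = t_mod, p_mod
    else:
        t_use, p_use = t_ord, p_ord

    q = bh_fdr(p_use)
    out = pd.DataFrame({
        "effect": effect,
        "t": t_use,
        "p": p_use,
        "p_ordinary": p_ord,
        "q": q,
        "direction": np.where(effect < 0, "down", "up"),
    }, index=study.expr.index)
    out.index.name = "gene_id"
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * n / j on the sorted p-values, capped at 1,
    mapped back to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# litter-restricted permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationReport:
    total: int
    count_ge_observed: int
    observed: int
    alpha: float
    sampled: bool = False
    seed: int | None = None
    tallies: list = field(default_factory=list, repr=False)

    @property
    def empirical_p(self) -> float:
        return self.count_ge_observed / self.total

    def summary(self) -> str:
        kind = "sampled" if self.sampled else "exhaustive"
        return (f"{self.observed} genes at p<{self.alpha:g}; "
                f"{self.count_ge_observed} of {self.total} {kind} "
                f"litter-restricted label permutations reach >= the observed "
                f"tally (empirical p = {self.empirical_p:.4g})")


def _litter_assignments(meta: pd.DataFrame):
    """All genotype-label assignments preserving each litter's genotype counts."""
    litters = list(dict.fromkeys(meta["litter"]))
    per_litter = []
    for lit in litters:
        idx = np.flatnonzero((meta["litter"] == lit).to_numpy())
        n_wt = int((meta.iloc[idx]["genotype"] == "wt").sum())
        per_litter.append([set(c) for c in itertools.combinations(idx.tolist(), n_wt)])
    for combo in itertools.product(*per_litter):
        wt_idx = set().union(*combo) if combo else set()
        labels = np.array(["wt" if i in wt_idx else "mut" for i in range(len(meta))])
        yield labels


def count_litter_permutations(meta: pd.DataFrame) -> int:
    total = 1
    for lit, grp in meta.groupby("litter"):
        total *= math.comb(len(grp), int((grp["genotype"] == "wt").sum()))
    return total


def litter_permutation_test(study: ExpressionStudy, alpha: float = 0.01,
                            moderate: bool = True, max_enumerate: int = 1_000_000,
                            n_sample: int = 1000, seed: int = 0
                            ) -> PermutationReport:
    """Permutation test of the differential-expression tally.

    Enumerates every reassignment of genotype labels that preserves each
    litter's genotype counts (the identity assignment included), refits the
    model for each, counts genes with p < alpha, and reports how many
    permutations reach at least the observed tally. If the enumeration
    exceeds `max_enumerate`, falls back to uniform sampling with a recorded
    seed (the identity assignment is still counted).
    """
    meta = study.meta
    total = count_litter_permutations(meta)
    observed = None
    tallies = []

    def tally(labels: np.ndarray) -> int:
        perm_meta = meta.copy()
        perm_meta["genotype"] = labels
        perm_study = ExpressionStudy(expr=study.expr, meta=perm_meta,
                                     detection=study.detection)
        res = fit_de(perm_study, moderate=moderate)
        return int((res["p"] < alpha).sum())

    observed = tally(meta["genotype"].to_numpy())

    sampled = total > max_enumerate
    if not sampled:
        for labels in _litter_assignments(meta):
            tallies.append(tally(labels))
    else:
        rng = np.random.default_rng(seed)
        tallies.append(observed)  # identity is always a valid permutation
        for _ in range(n_sample - 1):
            labels = meta["genotype"].to_numpy().copy()
            for lit in meta["litter"].unique():
                idx = np.flatnonzero((meta["litter"] == lit).to_numpy())
                labels[idx] = rng.permutation(labels[idx])
            tallies.append(tally(labels))

    count_ge = int(sum(1 for t in tallies if t >= observed))
    return PermutationReport(total=total if not sampled else len(tallies),
                             count_ge_observed=count_ge, observed=observed,
                             alpha=alpha, sampled=sampled,
                             seed=seed if sampled else None, tallies=tallies)
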