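"""Empirical null threshold and enriched-promoter calling.

The significance cutoff for wild-type enrichment is derived from the
window-score distribution of the knockout (protein-null) control arrays:
the non-specific signal the ChIP protocol produces when there is no
protein to pull down. The default rule takes the order statistic at rank
floor(0.99 * n) + 1, which guarantees that at least 99% of null window
scores lie strictly below the threshold whenever that order statistic is
unique. Comparison conventions follow the original analysis: calling uses
>= threshold; null-based exclusion uses > threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TilingDesign

log = logging.getLogger(__name__)

STRICT_THRESHOLD = 1.5  # window-score cutoff for the high-confidence tier


@dataclass(frozen=True)
class NullThreshold:
    value: float
    percentile: float
    n_null: int
    n_ties: int = 0


def derive_null_threshold(null_window_scores, percentile: float = 0.99,
                          method: str = "rank") -> NullThreshold:
    """Threshold excluding `percentile` of the null window scores.

    method="rank" (default): order statistic at rank floor(p*n) + 1 (capped
    at n), the exclusion-guaranteeing rule. method="interpolate": linear
    interpolation between order statistics (numpy's default percentile).
    Ties at the threshold value are counted and reported; if every null
    score is identical the threshold degenerates to that value (warned).
    """
    x = np.sort(np.asarray(null_window_scores, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError(f"need at least 100 null window scores, got {n}")
    if method == "rank":
        rank = min(n, int(np.floor(percentile * n)) + 1)
        value = float(x[rank - 1])
    elif method == "interpolate":
        value = float(np.percentile(x, 100.0 * percentile))
    else:
        raise ValueError(f"unknown method {method!r}")
    ties = int((x == value).sum())
    if x[0] == x[-1]:
        warnings.warn("all null window scores are identical; threshold is degenerate",
                      stacklevel=2)
    elif ties > 1:
        log.info("null threshold %.4f is attained by %d tied scores", value, ties)
    return NullThreshold(value=value, percentile=percentile, n_null=n, n_ties=ties)


def call_enriched_promoters(window_track: pd.Series, design: TilingDesign,
                            threshold: float, tier: str = "long",
                            min_enriched_probes: int = 1) -> pd.DataFrame:
    """Call promoter regions with >= `min_enriched_probes` window scores >= threshold.

    The peak interval of a called region is the maximal contiguous run of
    probes with window score >= threshold that contains the argmax probe,
    reported as the genomic interval from the first to the last probe
    midpoint of the run — the most likely stretch for the binding event.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    rows = []
    chrom_by_prom = design.probes.drop_duplicates("promoter_id"
                                                  ).set_index("promoter_id")["chrom"]
    for pid, probe_ids, mids in design.promoter_groups():
        w = window_track.reindex(probe_ids).to_numpy(dtype=float)
        enriched = w >= threshold
        if enriched.sum() < min_enriched_probes:
            continue
        imax = int(np.argmax(w))
        lo = imax
        while lo > 0 and enriched[lo - 1]:
            lo -= 1
        hi = imax
        while hi < len(w) - 1 and enriched[hi + 1]:
            hi += 1
        rows.append({
            "promoter_id": pid,
            "chrom": chrom_by_prom[pid],
            "peak_start": float(mids[lo]),
            "peak_end": float(mids[hi]),
            "max_window_score": float(w[imax]),
            "n_enriched_probes": int(enriched.sum()),
            "enriched_probe_ids": ",".join(np.asarray(probe_ids)[enriched]),
            "tier": tier,
        })
    cols = ["promoter_id", "chrom", "peak_start", "peak_end", "max_window_score",
            "n_enriched_probes", "enriched_probe_ids", "tier"]
    return pd.DataFrame(rows, columns=cols)


def map_regions_to_genes(calls: pd.DataFrame, design: TilingDesign) -> pd.DataFrame:
    """Expand region calls to one row per (region, gene) pair.

    Regions whose promoter lies near more than one TSS contribute one row
    per linked gene, so the unique-gene count can exceed the region count.
    Regions with no gene link are retained with an empty gene field.
    """
    merged = calls.merge(design.genes, on="promoter_id", how="left")
    n_orphan = int(merged["gene_id"].isna().sum())
    if n_orphan:
        log.warning("%d called region(s) have no gene link; kept with empty gene",
                    n_orphan)
        merged["gene_id"] = merged["gene_id"].fillna("")
    return merged


def filter_against_null(gene_calls: pd.DataFrame, null_window_track: pd.Series,
                        null_threshold: NullThreshold, design: TilingDesign
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove called genes whose promoter is also enriched in the null arrays.

    A gene is excluded when its promoter region contains at least one
    null-genotype probe with window score strictly above the null threshold
    (the same curation the strict tier receives). Returns (curated calls,
    exclusions table carrying the offending null evidence). Idempotent and
    order-independent.
    """
    prom = design.probes.groupby("promoter_id")["probe_id"].agg(list)
    offending: dict[str, tuple[str, float]] = {}
    for pid, probe_ids in prom.items():
        w = null_window_track.reindex(probe_ids).to_numpy(dtype=float)
        above = w > null_threshold.value
        if above.any():
            i = int(np.argmax(w))
            offending[pid] = (probe_ids[i], float(w[i]))

    mask = gene_calls["promoter_id"].isin(offending)
    excluded = gene_calls.loc[mask].copy()
    if len(excluded):
        excluded["null_probe_id"] = [offending[p][0] for p in excluded["promoter_id"]]
        excluded["null_window_score"] = [offending[p][1] for p in excluded["promoter_id"]]
    else:
        excluded["null_probe_id"] = pd.Series(dtype=str)
        excluded["null_window_score"] = pd.Series(dtype=float)
    kept = gene_calls.loc[~mask].reset_index(drop=True)
    return kept, excluded.reset_index(drop=True)


def write_region_bed(calls: pd.DataFrame, path) -> None:
    """Write peak intervals as BED (0-based half-open, midpoints rounded down)."""
    bed = pd.DataFrame({
        "chrom": calls["chrom"],
        "start": calls["peak_start"].astype(float).astype(int),
        "end": calls["peak_end"].astype(float).astype(int) + 1,
        "name": calls["promoter_id"],
        "score": calls["max_window_score"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False, float_format="%.4f")
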