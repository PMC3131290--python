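"""End-to-end driver: simulate -> normalize -> score -> call -> motifs -> DE -> integrate.

The driver exists so that one seed reproduces one study: every stage is a
thin call into the corresponding module and all intermediate artifacts are
returned (and optionally written) for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import calling, integrate, simulate
from .calling import STRICT_THRESHOLD
from .config import SimConfig
from .design import TilingDesign, write_design
from .expression import ExpressionStudy, detection_filter, fit_de, litter_permutation_test, qc_outliers
from .normalize import genotype_probe_scores
from .windows import WindowParams, window_scores


@dataclass
class StudyResult:
    config: SimConfig
    design: TilingDesign
    truth: simulate.SyntheticTruth
    wt_probe_scores: pd.Series
    null_probe_scores: pd.Series
    wt_window: pd.Series
    null_window: pd.Series
    threshold: calling.NullThreshold
    long_calls: pd.DataFrame
    strict_calls: pd.DataFrame
    long_genes: pd.DataFrame
    strict_genes: pd.DataFrame
    long_curated: pd.DataFrame
    strict_curated: pd.DataFrame
    exclusions: pd.DataFrame
    motifs: list = field(default_factory=list)
    de_result: pd.DataFrame | None = None
    permutation: object = None
    integration: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)


def run_study(cfg: SimConfig, outdir: str | Path | None = None,
              window_params: WindowParams = WindowParams(),
              de_alpha: float = 0.01, motif_alpha: float = 0.05,
              run_permutation: bool = True,
              strict_threshold: float = STRICT_THRESHOLD) -> StudyResult:
    """Run the whole synthetic study once under one seed."""
    design = simulate.gen_design(cfg)
    wt, ko, chip_truth = simulate.gen_chip_arrays(design, cfg)

    wt_scores = genotype_probe_scores(wt)
    ko_scores = genotype_probe_scores(ko)
    wt_window = window_scores(wt_scores, design, window_params)
    ko_window = window_scores(ko_scores, design, window_params)

    threshold = calling.derive_null_threshold(ko_window.to_numpy())
    long_calls = calling.call_enriched_promoters(wt_window, design,
                                                 threshold.value, tier="long")
    strict_calls = calling.call_enriched_promoters(wt_window, design,
                                                   strict_threshold, tier="strict")
    long_genes = calling.map_regions_to_genes(long_calls, design)
    strict_genes = calling.map_regions_to_genes(strict_calls, design)
    long_curated, exclusions = calling.filter_against_null(
        long_genes, ko_window, threshold, design)
    strict_curated, _ = calling.filter_against_null(
        strict_genes, ko_window, threshold, design)

    # motif scan: strict-tier target promoters vs a size-matched background
    target_proms = sorted(set(strict_curated["promoter_id"]))
    all_proms = design.promoter_ids
    background_proms = [p for p in all_proms if p not in set(target_proms)]
    background_proms = background_proms[:max(len(target_proms), 10)]
    motifs = []
    if len(target_proms) >= 2 and len(background_proms) >= 10:
        seqs, seq_truth = simulate.gen_promoter_sequences(
            cfg, target_proms, background_proms)
        from .motifs import enumerate_and_test
        motifs = enumerate_and_test({p: seqs[p] for p in target_proms},
                                    {p: seqs[p] for p in background_proms},
                                    alpha=motif_alpha)
    else:
        seq_truth = simulate.SyntheticTruth(seed=cfg.seed)

    # expression arm shares the design's gene namespace so integration is real
    study, expr_truth = simulate.gen_expression(
        cfg, gene_ids=sorted(design.genes["gene_id"]))
    study = detection_filter(study)
    flags = qc_outliers(study)
    if flags.any():
        study = study.subset_samples(flags.index[~flags])
    de = fit_de(study)
    perm = litter_permutation_test(study, alpha=de_alpha, seed=cfg.seed) \
        if run_permutation else None

    # integration
    chip_tiers = {}
    for _, row in long_curated.iterrows():
        if row["gene_id"]:
            chip_tiers[row["gene_id"]] = "long"
    for _, row in strict_curated.iterrows():
        if row["gene_id"]:
            chip_tiers[row["gene_id"]] = "strict"
    de_sig = de.loc[de["p"] < de_alpha]
    de_status = dict(zip(de_sig.index, de_sig["direction"]))
    overlap = integrate.overlap_genes(chip_tiers.keys(), de_status.keys())
    classified = integrate.classify(chip_tiers, de_status)

    truth = simulate.SyntheticTruth(
        bound_promoters=chip_truth.bound_promoters,
        de_genes=expr_truth.de_genes,
        motif_positions=seq_truth.motif_positions,
        seed=cfg.seed)

    stage_counts = {
        "probes": len(design.probes),
        "window_enriched_probes": int((wt_window >= threshold.value).sum()),
        "long_regions": len(long_calls),
        "long_genes": int(long_genes["gene_id"].replace("", pd.NA).nunique()),
        "long_curated_genes": int(long_curated["gene_id"].replace("", pd.NA).nunique()),
        "strict_regions": len(strict_calls),
        "strict_genes": int(strict_genes["gene_id"].replace("", pd.NA).nunique()),
        "strict_curated_genes": int(strict_curated["gene_id"].replace("", pd.NA).nunique()),
        "null_excluded_genes": int(exclusions["gene_id"].replace("", pd.NA).nunique()),
    }
    n_sig = int((de["p"] < de_alpha).sum())
    de_summary = {
        "genes_tested": len(de),
        f"significant_p<{de_alpha:g}": n_sig,
        "down_in_mutant": int(((de["p"] < de_alpha) & (de["direction"] == "down")).sum()),
        "up_in_mutant": int(((de["p"] < de_alpha) & (de["direction"] == "up")).sum()),
        "significant_fdr<0.05": int((de["q"] < 0.05).sum()),
        "qc_outliers_removed": int(flags.sum()),
    }
    artifacts = {
        "config": cfg.to_dict(),
        "threshold": threshold,
        "strict_threshold": strict_threshold,
        "stage_counts": stage_counts,
        "long_genes": long_curated,
        "strict_genes": strict_curated,
        "motifs": motifs,
        "de_summary": de_summary,
        "permutation": perm,
        "integration": {
            "overlap": overlap,
            "classes": classified["classification"].value_counts().to_dict(),
        },
    }

    result = StudyResult(
        config=cfg, design=design, truth=truth,
        wt_probe_scores=wt_scores, null_probe_scores=ko_scores,
        wt_window=wt_window, null_window=ko_window,
        threshold=threshold,
        long_calls=long_calls, strict_calls=strict_calls,
        long_genes=long_genes, strict_genes=strict_genes,
        long_curated=long_curated, strict_curated=strict_curated,
        exclusions=exclusions, motifs=motifs, de_result=de,
        permutation=perm,
        integration={"overlap": overlap, "table": classified},
        artifacts=artifacts)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_design(design, outdir / "probes.bed", outdir / "genes.tsv")
        truth.write(outdir / "truth")
        calling.write_region_bed(long_calls, outdir / "long_regions.bed")
        calling.write_region_bed(strict_calls, outdir / "strict_regions.bed")
        long_curated.to_csv(outdir / "long_curated_genes.tsv", sep="\t", index=False)
        strict_curated.to_csv(outdir / "strict_curated_genes.tsv", sep="\t", index=False)
        exclusions.to_csv(outdir / "null_exclusions.tsv", sep="\t", index=False)
        de.to_csv(outdir / "de_results.tsv", sep="\t")
        classified.to_csv(outdir / "integrated_targets.tsv", sep="\t", index=False)
        integrate.write_report(artifacts, outdir / "report.txt")
    return result
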