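"""ChIP x expression integration and the run report.

Genes bound in the ChIP screen and changed in the expression screen are
direct regulated targets; genes bound but unchanged are direct
bound-only targets (binding without detectable transcriptional
consequence in the profiled tissue); genes changed but not bound are
indirect targets, downstream of the factor's direct programme.
"""

from __future__ import annotations

import logging

import pandas as pd

log = logging.getLogger(__name__)


def _normalize(genes) -> list[str]:
    return [str(g).strip().upper() for g in genes if str(g).strip()]


def overlap_genes(chip_genes, de_genes) -> tuple[set, int, float]:
    """Intersection of the ChIP target genes with the DE genes.

    Identifiers are case-normalized; duplicates are collapsed with a
    warning. Returns (intersection set, its size, percentage of DE genes
    bound, rounded to 1 decimal).
    """
    chip = _normalize(chip_genes)
    de = _normalize(de_genes)
    for name, lst in (("chip", chip), ("de", de)):
        if len(lst) != len(set(lst)):
            log.warning("duplicate gene ids collapsed in the %s list", name)
    chip_set, de_set = set(chip), set(de)
    inter = chip_set & de_set
    pct = round(100.0 * len(inter) / len(de_set), 1) if de_set else 0.0
    return inter, len(inter), pct


def classify(chip_tiers: dict, de_status: dict) -> pd.DataFrame:
    """Partition every gene seen by either screen into one class.

    chip_tiers: gene -> 'long' | 'strict'; de_status: gene -> 'up' | 'down'.
    direct-regulated = bound and changed; direct-bound-only = bound only;
    indirect = changed only.
    """
    chip = {str(g).strip().upper(): t for g, t in chip_tiers.items()}
    de = {str(g).strip().upper(): s for g, s in de_status.items()}
    rows = []
    for gene in sorted(set(chip) | set(de)):
        tier = chip.get(gene, "none")
        status = de.get(gene, "none")
        if tier != "none" and status != "none":
            cls = "direct-regulated"
        elif tier != "none":
            cls = "direct-bound-only"
        else:
            cls = "indirect"
        rows.append((gene, tier, status, cls))
    return pd.DataFrame(rows, columns=["gene_id", "chip_tier", "de_status",
                                       "classification"])


def write_report(artifacts: dict, path) -> None:
    """Write the structured text run report.

    `artifacts` carries the per-stage outputs of a pipeline run (see
    pipeline.run_study). The body is deterministic for a fixed seed: no
    timestamps. Missing upstream artifacts raise.
    """
    required = ["config", "threshold", "stage_counts", "long_genes", "strict_genes",
                "motifs", "de_summary", "permutation", "integration"]
    missing = [k for k in required if k not in artifacts]
    if missing:
        raise ValueError(f"cannot write report; missing upstream artifact(s): {missing}")

    cfg = artifacts["config"]
    thr = artifacts["threshold"]
    counts = artifacts["stage_counts"]
    lines = []
    w = lines.append
    w("# nullchip run report")
    w("")
    w("## configuration")
    for key, val in sorted(cfg.items()):
        w(f"  {key} = {val}")
    w("")
    w("## null calibration")
    w(f"  threshold = {thr.value:.6f} (percentile {thr.percentile}, "
      f"n_null = {thr.n_null}, ties = {thr.n_ties})")
    w(f"  strict threshold = {artifacts.get('strict_threshold', 'n/a')}")
    w("")
    w("## stage counts (probes -> window-enriched -> regions -> genes -> curated)")
    for key, val in counts.items():
        w(f"  {key} = {val}")
    w("")
    w("## motifs (pattern, target promoter count, p_min, p_max)")
    for m in artifacts["motifs"]:
        w(f"  {m.label}\t{m.promoter_count}\t{m.p_min:.3g}\t{m.p_max:.3g}")
    if not artifacts["motifs"]:
        w("  (none below alpha)")
    w("")
    w("## differential expression")
    for key, val in artifacts["de_summary"].items():
        w(f"  {key} = {val}")
    w("")
    w("## litter-restricted permutation test")
    perm = artifacts["permutation"]
    w(f"  {perm.summary()}" if perm is not None else "  (not run)")
    w("")
    w("## integration")
    inter, n_common, pct = artifacts["integration"]["overlap"]
    w(f"  chip x de overlap = {n_common} genes ({pct}% of DE genes)")
    cls = artifacts["integration"]["classes"]
    for name, n in cls.items():
        w(f"  {name} = {n}")
    w("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
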