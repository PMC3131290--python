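"""Tiling-array geometry: probes, promoter regions and their gene links.

Coordinates are 0-based half-open on disk (BED convention). All distance
computations in the pipeline use the probe interval midpoint, which may be
half-integral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PROBE_COLUMNS = ["chrom", "start", "end", "probe_id", "promoter_id"]
GENE_COLUMNS = ["promoter_id", "gene_id", "tss", "strand"]


class DesignError(ValueError):
    pass


@dataclass
class TilingDesign:
    """Array geometry shared by every scoring stage.

    probes: one row per probe (chrom, start, end, probe_id, promoter_id),
        sorted by (promoter_id, start).
    genes: one row per promoter->gene link; a promoter region that lies
        between two divergent TSSs carries two rows.
    """

    probes: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.probes = self.probes.reset_index(drop=True)
        if self.probes["probe_id"].duplicated().any():
            dup = self.probes.loc[self.probes["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise DesignError(f"duplicate probe_id {dup!r}")
        if (self.probes["end"] < self.probes["start"]).any():
            raise DesignError("probe intervals must have non-negative length")
        known = set(self.genes["promoter_id"])
        missing = self.probes.loc[~self.probes["promoter_id"].isin(known)]
        if len(missing):
            row = missing.iloc[0]
            raise DesignError(
                f"probe {row['probe_id']!r} references unknown promoter {row['promoter_id']!r}"
            )
        self.probes = self.probes.sort_values(
            ["promoter_id", "start"], kind="mergesort"
        ).reset_index(drop=True)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.probes["probe_id"])

    @property
    def promoter_ids(self) -> list[str]:
        return sorted(self.genes["promoter_id"].unique())

    def midpoints(self) -> pd.Series:
        """Probe midpoints, indexed by probe_id (may be half-integral)."""
        mid = (self.probes["start"] + self.probes["end"]) / 2.0
        return pd.Series(mid.to_numpy(), index=self.probes["probe_id"].to_numpy(),
                         name="midpoint")

    def promoter_groups(self):
        """Iterate (promoter_id, probe_id array, midpoint array), midpoint-sorted."""
        mids = (self.probes["start"] + self.probes["end"]) / 2.0
        df = pd.DataFrame({
            "probe_id": self.probes["probe_id"],
            "promoter_id": self.probes["promoter_id"],
            "mid": mids,
        })
        for pid, grp in df.groupby("promoter_id", sort=True):
            grp = grp.sort_values("mid", kind="mergesort")
            yield pid, grp["probe_id"].to_numpy(), grp["mid"].to_numpy()

    def genes_for_promoter(self, promoter_id: str) -> list[str]:
        return self.genes.loc[self.genes["promoter_id"] == promoter_id, "gene_id"].tolist()


def read_design(probe_path, gene_path) -> TilingDesign:
    """Read a BED-like probe table and a promoter->gene TSV into a design.

    Probes whose interval does not overlap [TSS - upstream, TSS + downstream]
    of their promoter are not second-guessed here; geometry checks belong to
    the generator. Probes referencing unknown promoters raise; duplicate
    probe ids raise.
    """
    probes = pd.read_csv(probe_path, sep="\t", header=None, names=PROBE_COLUMNS,
                         comment="#", dtype={"chrom": str, "probe_id": str,
                                             "promoter_id": str})
    genes = pd.read_csv(gene_path, sep="\t", dtype={"promoter_id": str, "gene_id": str,
                                                    "strand": str})
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise DesignError(f"promoter/gene table missing columns {missing}")
    orphan = genes.loc[~genes["promoter_id"].isin(set(probes["promoter_id"]))]
    if len(orphan):
        log.warning("%d promoter(s) in the gene table have no probes; kept as annotation",
                    len(orphan))
    return TilingDesign(probes=probes, genes=genes[GENE_COLUMNS].copy())


def write_design(design: TilingDesign, probe_path, gene_path) -> None:
    design.probes[PROBE_COLUMNS].to_csv(probe_path, sep="\t", header=False, index=False)
    design.genes[GENE_COLUMNS].to_csv(gene_path, sep="\t", index=False)
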