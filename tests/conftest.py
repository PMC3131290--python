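import numpy as np
import pandas as pd
import pytest

from nullchip.design import TilingDesign


def make_design(promoter_midpoints: dict, probe_len: int = 60,
                genes: dict | None = None) -> TilingDesign:
    """Build a design from {promoter_id: [probe midpoints]} by hand.

    `genes` optionally maps promoter_id -> list of gene ids (default one
    gene per promoter).
    """
    probe_rows, gene_rows = [], []
    for pid, mids in promoter_midpoints.items():
        for j, mid in enumerate(mids):
            start = int(mid - probe_len / 2)
            probe_rows.append(("chr1", start, start + probe_len, f"{pid}_p{j:02d}", pid))
        linked = (genes or {}).get(pid, [f"gene_{pid}"])
        for g in linked:
            gene_rows.append((pid, g, int(min(mids)), "+"))
    return TilingDesign(
        probes=pd.DataFrame(probe_rows,
                            columns=["chrom", "start", "end", "probe_id", "promoter_id"]),
        genes=pd.DataFrame(gene_rows, columns=["promoter_id", "gene_id", "tss", "strand"]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_design():
    """One 3-probe promoter plus a bidirectional 2-gene promoter."""
    return make_design(
        {"PA": [100, 400, 700], "PB": [100, 350, 600, 850]},
        genes={"PA": ["geneA"], "PB": ["geneB1", "geneB2"]},
    )
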