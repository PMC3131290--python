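"""Window-adjusted enrichment scores.

Each probe's window score is the median of its own probe score and its
nearest neighbouring probe on either side, neighbours counting only when
their midpoint lies within the half-width (default 500 bp). If fewer than
`min_probes` members of that window set have a probe score above
background, the window score is zero — this guards against artificial
skewing of enrichment values at the edges of promoter regions, where a
probe has fewer flanking observations. Windows never cross promoter-region
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TilingDesign


@dataclass(frozen=True)
class WindowParams:
    halfwidth_bp: float = 500.0
    min_probes: int = 3
    background_level: float = 0.0
    #: "nearest" = at most one neighbour per side (window set size <= 3);
    #: "all-in-window" = every probe within +/- halfwidth_bp
    mode: str = "nearest"

    def __post_init__(self) -> None:
        if self.halfwidth_bp <= 0:
            raise ValueError("halfwidth must be positive")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if self.mode not in ("nearest", "all-in-window"):
            raise ValueError(f"unknown window mode {self.mode!r}")


def _window_members(mids: np.ndarray, i: int, params: WindowParams) -> list[int]:
    if params.mode == "nearest":
        members = [i]
        if i > 0 and mids[i] - mids[i - 1] <= params.halfwidth_bp:
            members.append(i - 1)
        if i < len(mids) - 1 and mids[i + 1] - mids[i] <= params.halfwidth_bp:
            members.append(i + 1)
        return members
    return [j for j in range(len(mids))
            if abs(mids[j] - mids[i]) <= params.halfwidth_bp]


def window_scores(probe_scores: pd.Series, design: TilingDesign,
                  params: WindowParams = WindowParams()) -> pd.Series:
    """Window-adjusted score for every probe in the design.

    `probe_scores` is indexed by probe_id (replicate-mean, zero-clipped).
    Returns a Series on the same probes. Probes in single-probe promoters
    or with too-distant neighbours get 0 by the min_probes rule.
    """
    values = {}
    for _, probe_ids, mids in design.promoter_groups():
        s = probe_scores.reindex(probe_ids).to_numpy(dtype=float)
        for i, pid in enumerate(probe_ids):
            members = _window_members(mids, i, params)
            member_scores = s[members]
            if (member_scores > params.background_level).sum() < params.min_probes:
                values[pid] = 0.0
            else:
                values[pid] = float(np.median(member_scores))
    out = probe_scores.copy()
    out.loc[:] = [values[p] for p in out.index]
    out.name = "window_score"
    return out
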