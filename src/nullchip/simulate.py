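"""Synthetic tiling-array, expression and promoter-sequence generator.

Every downstream stage of the pipeline (normalization, window scoring,
null-calibrated target calling, motif enrichment, litter-aware differential
expression, integration) is testable against the ground truth this module
records, with no external download.

A note on geometry: ~25 probes at 100-300 bp spacing tile roughly 5 kb,
less than the nominal 8 kb promoter span (5.5 kb upstream to 2.5 kb
downstream of the TSS). Probes are laid down from the upstream end until
the probe budget or the downstream boundary is exhausted, and planted
binding sites are drawn inside the tiled interval so that every true peak
is observable by the array.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from .design import TilingDesign
from .motifs import parse_pattern

# fixed per-component RNG stream keys so the four generators are
# independent but jointly deterministic under one cfg.seed
_STREAM_DESIGN, _STREAM_CHIP, _STREAM_EXPR, _STREAM_SEQ = 11, 13, 17, 19


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study.

    bound_promoters: promoter_id, site_pos (genomic), site_offset
        (strand-oriented, relative to the first gene's TSS), amplitude.
    de_genes: gene_id, effect (signed log2, mutant minus wild-type).
    motif_positions: seq_id, position, variant (concrete planted word).
    """

    bound_promoters: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["promoter_id", "site_pos", "site_offset", "amplitude"]))
    de_genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "effect"]))
    motif_positions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["seq_id", "position", "variant"]))
    seed: int = 0

    def write(self, prefix) -> None:
        prefix = str(prefix)
        for name in ("bound_promoters", "de_genes", "motif_positions"):
            df = getattr(self, name)
            with open(f"{prefix}.{name}.tsv", "w") as fh:
                fh.write(f"# seed={self.seed}\n")
                df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, prefix) -> "SyntheticTruth":
        prefix = str(prefix)
        parts, seed = {}, 0
        for name in ("bound_promoters", "de_genes", "motif_positions"):
            path = f"{prefix}.{name}.tsv"
            with open(path) as fh:
                header = fh.readline().strip()
                seed = int(header.split("seed=")[1])
                parts[name] = pd.read_csv(fh, sep="\t")
        return cls(seed=seed, **parts)


# ---------------------------------------------------------------------------
# array design
# ---------------------------------------------------------------------------

def gen_design(cfg: SimConfig) -> TilingDesign:
    """Generate the tiling-array geometry.

    Each promoter sits on its own stretch of a chromosome; probe offsets
    are strand-oriented relative to the TSS, with consecutive gaps drawn
    uniformly from the configured spacing range, starting at the upstream
    boundary. A configured fraction of promoter regions is linked to a
    second, divergently transcribed gene.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_DESIGN)
    up, down = cfg.promoter_span_bp
    plen = cfg.probe_length_bp
    lo, hi = cfg.probe_spacing_bp

    probe_rows, gene_rows = [], []
    region_pitch = up + down + 20_000  # gap so regions never abut
    n_bidir = int(round(cfg.bidirectional_fraction * cfg.n_promoters))
    bidir = np.zeros(cfg.n_promoters, dtype=bool)
    if n_bidir:
        bidir[rng.choice(cfg.n_promoters, size=n_bidir, replace=False)] = True

    for i in range(cfg.n_promoters):
        pid = f"P{i:05d}"
        chrom = f"chr{i % 19 + 1}"
        tss = 1_000_000 + (i // 19) * region_pitch + up
        strand = "+" if rng.random() < 0.5 else "-"

        n_probes = max(2, int(rng.poisson(cfg.probes_per_promoter_mean)))
        offset = -up + float(rng.integers(0, lo))
        offsets = []
        while len(offsets) < n_probes and offset <= down - plen:
            offsets.append(offset)
            offset += float(rng.integers(lo, hi + 1))
        for j, off in enumerate(offsets):
            if strand == "+":
                start = tss + off
            else:
                start = tss - off - plen
            probe_rows.append((chrom, int(start), int(start) + plen,
                               f"{pid}_p{j:02d}", pid))

        gene_rows.append((pid, f"G{i:05d}", int(tss), strand))
        if bidir[i]:
            other = "-" if strand == "+" else "+"
            gene_rows.append((pid, f"G{i:05d}b", int(tss) + 500, other))

    probes = pd.DataFrame(probe_rows,
                          columns=["chrom", "start", "end", "probe_id", "promoter_id"])
    genes = pd.DataFrame(gene_rows, columns=["promoter_id", "gene_id", "tss", "strand"])
    return TilingDesign(probes=probes, genes=genes)


# ---------------------------------------------------------------------------
# ChIP log-ratio replicates
# ---------------------------------------------------------------------------

def _peak_kernel(dist: np.ndarray, amplitude: float, halfwidth: float,
                 shape: str) -> np.ndarray:
    if shape == "triangular":
        return amplitude * np.maximum(0.0, 1.0 - np.abs(dist) / halfwidth)
    # gaussian alternative: same amplitude, sd chosen so the kernel is
    # small (~1% of peak) at +/- halfwidth
    sigma = halfwidth / 3.0
    return amplitude * np.exp(-0.5 * (dist / sigma) ** 2)


def gen_chip_arrays(design: TilingDesign, cfg: SimConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate wild-type and null-genotype replicate log-ratio matrices.

    Null replicates are pure zero-mean Gaussian noise (no Foxp2 protein, no
    specific pulldown); wild-type replicates add, for each bound promoter, a
    peak of enrichment centred on the planted binding site whose expected
    log2 enrichment decays to zero at +/- peak_halfwidth_bp — the shape
    expected when sheared fragments of bounded size overlap a point source.
    """
    cfg.validate()
    if cfg.peak_amplitude_log2 < 0:
        raise ConfigError("peak amplitude must be >= 0")
    rng = _rng(cfg, _STREAM_CHIP)

    mids = design.midpoints()
    probe_ids = mids.index.to_numpy()
    n = len(probe_ids)
    nrep = cfg.n_replicates_per_genotype

    promoters = design.promoter_ids
    n_bound = int(round(cfg.bound_fraction * len(promoters)))
    bound = sorted(rng.choice(promoters, size=n_bound, replace=False)) if n_bound else []

    tss_by_prom = design.genes.drop_duplicates("promoter_id").set_index("promoter_id")
    strand_by_prom = tss_by_prom["strand"]
    tss_by_prom = tss_by_prom["tss"]

    prom_of_probe = design.probes.set_index("probe_id")["promoter_id"]
    expected = pd.Series(0.0, index=mids.index)
    truth_rows = []

    def plant(promoter_id: str, amplitude: float, store: pd.Series) -> None:
        sel = prom_of_probe == promoter_id
        m = mids[sel.to_numpy()]
        lo_m, hi_m = float(m.min()), float(m.max())
        pad = min(400.0, (hi_m - lo_m) / 4.0)
        site = float(rng.uniform(lo_m + pad, hi_m - pad)) if hi_m - lo_m > 2 * pad \
            else (lo_m + hi_m) / 2.0
        store[sel.to_numpy()] += _peak_kernel(
            m.to_numpy() - site, amplitude, cfg.peak_halfwidth_bp, cfg.peak_shape)
        tss = float(tss_by_prom[promoter_id])
        sign = 1.0 if strand_by_prom[promoter_id] == "+" else -1.0
        truth_rows.append((promoter_id, site, sign * (site - tss), amplitude))

    for pid in bound:
        plant(pid, cfg.peak_amplitude_log2, expected)

    null_expected = pd.Series(0.0, index=mids.index)
    n_contam = int(round(cfg.null_contamination_fraction * len(promoters)))
    if n_contam:
        unbound = [p for p in promoters if p not in set(bound)]
        for pid in rng.choice(unbound, size=n_contam, replace=False):
            plant(pid, cfg.peak_amplitude_log2, null_expected)
            truth_rows.pop()  # contamination is noise, not a true target

    wt = expected.to_numpy()[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n, nrep))
    ko = null_expected.to_numpy()[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n, nrep))

    wt_df = pd.DataFrame(wt, index=probe_ids, columns=[f"wt_{r+1}" for r in range(nrep)])
    ko_df = pd.DataFrame(ko, index=probe_ids, columns=[f"ko_{r+1}" for r in range(nrep)])
    truth = SyntheticTruth(
        bound_promoters=pd.DataFrame(
            truth_rows, columns=["promoter_id", "site_pos", "site_offset", "amplitude"]),
        seed=cfg.seed)
    return wt_df, ko_df, truth


# ---------------------------------------------------------------------------
# expression study
# ---------------------------------------------------------------------------

def gen_expression(cfg: SimConfig, gene_ids=None, de_gene_pool=None):
    """Simulate the litter-structured expression study on the transformed scale.

    Per gene: value = baseline + genotype effect (truth genes only, applied
    to mutant samples) + a per-(gene, litter) random effect + iid noise.
    `gene_ids` lets the expression study share an identifier namespace with
    an array design (ids are padded or truncated to cfg.n_genes);
    `de_gene_pool` restricts which genes may be differentially expressed,
    so integration tests can plant DE inside the bound set.
    Returns (ExpressionStudy, SyntheticTruth).
    """
    from .expression import ExpressionStudy  # local import to avoid a cycle

    cfg.validate()
    rng = _rng(cfg, _STREAM_EXPR)

    sample_rows = []
    for li, (n_wt, n_mut) in enumerate(cfg.litters, start=1):
        if n_wt == 0 or n_mut == 0:
            warnings.warn(
                f"litter L{li} contains a single genotype; the restricted "
                "permutation test has no freedom within it", stacklevel=2)
        for _ in range(n_wt):
            sample_rows.append((f"s{len(sample_rows)+1:02d}", "wt", f"L{li}"))
        for _ in range(n_mut):
            sample_rows.append((f"s{len(sample_rows)+1:02d}", "mut", f"L{li}"))
    meta = pd.DataFrame(sample_rows, columns=["sample", "genotype", "litter"]
                        ).set_index("sample")
    n_samples = len(meta)

    if gene_ids is None:
        genes = [f"E{i:05d}" for i in range(cfg.n_genes)]
    else:
        genes = list(gene_ids)[:cfg.n_genes]
        genes += [f"E{i:05d}" for i in range(len(genes), cfg.n_genes)]
    baseline = rng.normal(cfg.expr_baseline_mean, cfg.expr_baseline_sd, cfg.n_genes)

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    if de_gene_pool is not None:
        pool = [i for i, g in enumerate(genes) if g in set(de_gene_pool)]
        if len(pool) < n_de:
            raise ConfigError("de_gene_pool smaller than the requested DE gene count")
        de_idx = np.sort(rng.choice(pool, size=n_de, replace=False)) if n_de else []
    else:
        de_idx = np.sort(rng.choice(cfg.n_genes, size=n_de, replace=False)) if n_de else []
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effects = np.zeros(cfg.n_genes)
    if n_de:
        effects[de_idx] = signs * cfg.effect_size_log2

    litter_codes = pd.Categorical(meta["litter"]).codes
    n_litters = len(cfg.litters)
    litter_fx = rng.normal(0.0, cfg.litter_sd, size=(cfg.n_genes, n_litters))
    is_mut = (meta["genotype"] == "mut").to_numpy().astype(float)

    values = (baseline[:, None]
              + effects[:, None] * is_mut[None, :]
              + litter_fx[:, litter_codes]
              + rng.normal(0.0, cfg.expr_noise_sd, size=(cfg.n_genes, n_samples)))

    expr = pd.DataFrame(values, index=genes, columns=meta.index)
    detection = pd.DataFrame(0.99, index=genes, columns=meta.index)

    study = ExpressionStudy(expr=expr, meta=meta, detection=detection)
    truth = SyntheticTruth(
        de_genes=pd.DataFrame({"gene_id": [genes[i] for i in de_idx],
                               "effect": effects[de_idx] if n_de else []}),
        seed=cfg.seed)
    return study, truth


def to_raw_intensities(study, cfg: SimConfig):
    """Thin raw-scale wrapper over the simulated signal.

    Maps the transformed-scale matrix back to intensity-like values
    (2^value), adds an array-specific additive background and noise, and
    returns (raw matrix, per-array negative-control means) as a substrate
    for the background-correction + variance-stabilization path.
    """
    rng = _rng(cfg, _STREAM_EXPR + 100)
    raw = np.power(2.0, study.expr.to_numpy())
    bg = rng.uniform(50.0, 150.0, size=raw.shape[1])
    raw = raw + bg[None, :] + rng.normal(0.0, 5.0, size=raw.shape)
    raw_df = pd.DataFrame(raw, index=study.expr.index, columns=study.expr.columns)
    controls = pd.Series(bg, index=study.expr.columns, name="control_mean")
    return raw_df, controls


# ---------------------------------------------------------------------------
# promoter sequences
# ---------------------------------------------------------------------------

def gen_promoter_sequences(cfg: SimConfig, target_ids, background_ids
                           ) -> tuple[dict[str, str], SyntheticTruth]:
    """Simulate promoter sequences with a planted degenerate 8-mer.

    Sequences are i.i.d. uppercase ACGT at the configured GC fraction. A
    random concrete instantiation of the planted degenerate motif is
    inserted at a random offset into `motif_prevalence_target` of the target
    promoters and `motif_prevalence_background` of the background promoters;
    plant positions are recorded in the truth. Chance occurrences of the
    planted motif are scrubbed from non-planted sequences (the matching
    window is redrawn), so each prevalence is the exact per-sequence
    presence probability of the planted motif, not a lower bound.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_SEQ)
    pattern = parse_pattern(cfg.planted_motif)
    if len(pattern) > cfg.sequence_length_bp:
        raise ConfigError("planted motif is longer than the simulated sequences")

    gc, at = cfg.gc_fraction / 2.0, (1.0 - cfg.gc_fraction) / 2.0
    bases = np.array(list("ACGT"))
    probs = np.array([at, gc, gc, at])

    from .motifs import reverse_complement_pattern

    pattern_rc = reverse_complement_pattern(pattern)
    k = len(pattern)

    def scrub(letters: np.ndarray) -> np.ndarray:
        """Redraw any window matching the planted motif on either strand."""
        for _ in range(100):  # resampling converges almost immediately
            seq = "".join(letters)
            dirty = [i for i in range(len(seq) - k + 1)
                     if all(seq[i + j] in p for j, p in enumerate(pattern))
                     or all(seq[i + j] in p for j, p in enumerate(pattern_rc))]
            if not dirty:
                return letters
            for i in dirty:
                letters[i:i + k] = rng.choice(bases, size=k, p=probs)
        raise RuntimeError("could not scrub chance motif occurrences")

    seqs: dict[str, str] = {}
    plant_rows = []
    for ids, prevalence in ((list(target_ids), cfg.motif_prevalence_target),
                            (list(background_ids), cfg.motif_prevalence_background)):
        for sid in ids:
            letters = rng.choice(bases, size=cfg.sequence_length_bp, p=probs)
            if rng.random() < prevalence:
                variant = "".join(sorted(p)[rng.integers(len(p))] for p in pattern)
                pos = int(rng.integers(0, cfg.sequence_length_bp - len(variant) + 1))
                letters[pos:pos + len(variant)] = list(variant)
                plant_rows.append((sid, pos, variant))
            else:
                letters = scrub(letters)
            seqs[sid] = "".join(letters)

    truth = SyntheticTruth(
        motif_positions=pd.DataFrame(plant_rows, columns=["seq_id", "position", "variant"]),
        seed=cfg.seed)
    return seqs, truth


def write_fasta(seqs: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio.SeqIO import parse as seqio_parse
    return {rec.id: str(rec.seq).upper() for rec in seqio_parse(str(path), "fasta")}


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6f")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
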