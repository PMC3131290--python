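"""Simulation configuration for the synthetic promoter-tiling study.

The defaults emulate the study design the pipeline was built for: an
Agilent-style promoter tiling array (~25 probes per promoter spanning
5.5 kb upstream to 2.5 kb downstream of the TSS at 100-300 bp spacing,
three biological replicates per genotype) and an Illumina WG-6-style
expression experiment with litter structure (three litters giving 5
wild-type and 6 mutant usable samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    # --- tiling array geometry ---
    n_promoters: int = 2000
    probes_per_promoter_mean: float = 25.0
    probe_spacing_bp: tuple[int, int] = (100, 300)
    promoter_span_bp: tuple[int, int] = (5500, 2500)  # (upstream, downstream) of TSS
    probe_length_bp: int = 60
    n_replicates_per_genotype: int = 3
    bidirectional_fraction: float = 0.05

    # --- ChIP signal ---
    noise_sd: float = 0.35                 # per-replicate log2-ratio noise
    bound_fraction: float = 0.05
    peak_amplitude_log2: float = 2.0
    peak_halfwidth_bp: float = 750.0       # midpoint of the 300-1000 bp shear range
    peak_shape: str = "triangular"         # or "gaussian"
    null_contamination_fraction: float = 0.0  # antibody cross-reactivity knob; off

    # --- expression study ---
    n_genes: int = 10000
    # (n wild-type, n mutant) per litter; default gives 5 WT + 6 mutant
    litters: tuple[tuple[int, int], ...] = ((2, 2), (2, 2), (1, 2))
    de_fraction: float = 0.02
    effect_size_log2: float = 1.5
    expr_noise_sd: float = 0.5
    litter_sd: float = 0.25
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 1.5

    # --- promoter sequences / motif planting ---
    planted_motif: str = "AAAG[G/C]AAA"
    motif_prevalence_target: float = 0.7
    motif_prevalence_background: float = 0.2
    sequence_length_bp: int = 800
    gc_fraction: float = 0.45

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_promoters <= 0:
            raise ConfigError("n_promoters must be positive")
        lo, hi = self.probe_spacing_bp
        if lo <= 0 or hi < lo:
            raise ConfigError(f"probe spacing range must be positive, got {self.probe_spacing_bp}")
        up, down = self.promoter_span_bp
        if up <= 0 or down <= 0:
            raise ConfigError("promoter span must be positive on both sides of the TSS")
        if self.peak_amplitude_log2 < 0:
            raise ConfigError("peak amplitude must be >= 0")
        for name in ("bound_fraction", "bidirectional_fraction", "de_fraction",
                     "motif_prevalence_target", "motif_prevalence_background",
                     "gc_fraction", "null_contamination_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.motif_prevalence_target < self.motif_prevalence_background:
            raise ConfigError("planted motif must be at least as prevalent in targets "
                              "as in background promoters")
        if self.n_replicates_per_genotype < 1:
            raise ConfigError("need at least one replicate per genotype")
        if self.peak_shape not in ("triangular", "gaussian"):
            raise ConfigError(f"unknown peak shape {self.peak_shape!r}")
        if not self.litters or any(w + m <= 0 for w, m in self.litters):
            raise ConfigError("each litter must contain at least one sample")

    def to_dict(self) -> dict:
        return asdict(self)
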