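"""Simulate a tiling-array study and call binding targets against the knockout null.

Generates wild-type and protein-null replicate arrays over 500 promoters
with 5% of promoters carrying a planted binding peak, scores probes and
windows, derives the empirical 99% null threshold, and calls the long and
strict target tiers.
"""

import nullchip as nc
from nullchip.normalize import genotype_probe_scores

cfg = nc.SimConfig(n_promoters=500, bound_fraction=0.05,
                   peak_amplitude_log2=2.0, noise_sd=0.35, seed=1)
design = nc.gen_design(cfg)
wt, ko, truth = nc.gen_chip_arrays(design, cfg)

wt_window = nc.window_scores(genotype_probe_scores(wt), design)
ko_window = nc.window_scores(genotype_probe_scores(ko), design)

threshold = nc.derive_null_threshold(ko_window.to_numpy())
long_calls = nc.call_enriched_promoters(wt_window, design, threshold.value, tier="long")
strict_calls = nc.call_enriched_promoters(wt_window, design, 1.5, tier="strict")

truth_set = set(truth.bound_promoters["promoter_id"])
long_set = set(long_calls["promoter_id"])
strict_set = set(strict_calls["promoter_id"])

print(f"null threshold (99% of knockout window scores): {threshold.value:.3f}")
print(f"  -> a window score of {threshold.value:.3f} means "
      f"{nc.fold_enrichment(threshold.value):.2f}-fold enrichment")
print(f"planted peaks: {len(truth_set)} promoters")
print(f"long tier  (>= threshold): {len(long_calls)} regions, "
      f"recall {len(truth_set & long_set) / len(truth_set):.2f}, "
      f"precision {len(truth_set & long_set) / len(long_set):.2f}")
print(f"strict tier (>= 1.5):      {len(strict_calls)} regions, "
      f"recall {len(truth_set & strict_set) / len(truth_set):.2f}, "
      f"precision {len(truth_set & strict_set) / max(len(strict_set), 1):.2f}")
print()
print("The long tier catches nearly every planted peak but, with i.i.d.")
print("array noise, also admits unbound promoters whose 25 correlated")
print("windows jointly exceed a probe-level 99% cutoff far more often than")
print("1% of the time; the strict 1.5 cutoff trades recall for precision.")
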