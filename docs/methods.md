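# Methods

This note records the models, the defaults and their rationale, the
numerical choices, and the known limits of what the synthetic studies can
demonstrate.

## Enrichment model and scoring

Arrays carry paired ChIP/input measurements per probe. Within-array
normalization removes intensity-dependent dye bias by a locally weighted
regression of M = log2(ChIP/input) on A = ½·log2(ChIP·input)
(span 0.3, 2 robustness iterations, tricube weights — the standard
M-A defaults; intensities are floored at 0.5 before logging, and arrays
with fewer than 20 probes fall back to median-centering). The span is a
bias/variance trade-off: strong curvature combined with very low probe
noise leaves a detectable residual trend at span 0.3; at array-realistic
noise (sd ≳ 0.2 log2 units) the residual trend is negligible. Quantile
normalization is applied across the replicates of each genotype
separately (wild-type and null arrays are never mixed before threshold
derivation), with ties mapped to averaged target values.

The probe score is `s = max(0, mean of replicate log-ratios)`, so
`fold = 2^s` and `s = 1` is 2-fold enrichment. Missing replicate values
are averaged over the available replicates rather than dropping the
probe, keeping the window lattice intact.

The window-adjusted score of a probe is the median of its own probe score
and its nearest neighbour on each side, neighbours counting only within
±500 bp of the probe midpoint (midpoint-to-midpoint distances; windows
never cross promoter-region boundaries). If fewer than 3 members of this
window set have score > 0, the window score is 0. The ±500 bp half-width
matches the ~1000 bp span of labelled sheared fragments: a true binding
event must be corroborated by adjacent probes, while an isolated hot
probe — or an edge probe with only one neighbour — scores zero. An
`all-in-window` mode (median over all probes within ±500 bp, same
zeroing count) is available for sensitivity analysis; the nearest-
neighbour reading is the default.

## Null calibration and calling

The significance threshold is derived from the window scores of the
protein-null (knockout) arrays: the order statistic at rank
`floor(0.99·n) + 1`. This rank rule guarantees that at least 99% of null
scores lie strictly below the threshold whenever the order statistic is
unique (ties are counted and reported; a linear-interpolation variant is
available behind a flag). Calling uses `>=` (threshold attained counts);
null-based exclusion uses `>` (strictly exceeding null evidence).

A promoter region is called when ≥1 of its probes reaches the threshold —
the window score itself already encodes the requirement of three locally
positive probes, so no separate multi-probe rule is imposed (a ≥2-probes
variant exists behind a parameter). The peak interval is the maximal
contiguous run of probes at/above threshold containing the argmax,
reported from first to last probe midpoint. Regions map to every gene
whose annotated TSS shares the promoter region (divergent gene pairs give
two rows); called genes whose promoter also carries null window scores
above the threshold are excluded, with the offending probe and score
recorded. The strict tier (window score ≥ 1.5) reuses the same null
filter.

### Promoter-level error under independent noise

The 99% rule controls the *probe-level* null exceedance exactly. A
promoter, however, contains ~25 overlapping windows; under independent
Gaussian array noise the chance that at least one of them exceeds a
probe-level 99% cutoff is roughly 15–20%, not 1%. On synthetic data this
makes the long tier highly sensitive (recall ≈ 1 at 2.0 log2 amplitude,
0.35 noise) but imprecise (precision ≈ 0.2 at a 5% bound fraction),
while the strict tier is near-pure. Real knockout arrays behave
differently: their above-threshold signal concentrates in a small number
of artifact-prone promoters (cross-reactivity, repetitive sequence), so
the same probe-level rule yields a promoter-level false rate near 1%.
The generator's independent-noise null is the cleanest testbed for the
calibration logic, but it cannot reproduce that clustering; an optional
contamination knob (off by default) plants artifact peaks in null arrays
for experiments on this point. Conclusions from the synthetic precision
figures therefore transfer to real arrays only as a lower bound on the
value of the strict tier and of the null exclusion filter.

## Synthetic arrays

Probes are laid down from the upstream boundary (−5.5 kb) with gaps drawn
uniformly from 100–300 bp until the probe budget (Poisson, mean 25) or
the downstream boundary (+2.5 kb) is exhausted; note 25 probes at this
spacing tile ~5 kb, so coverage does not span the full nominal region —
binding sites are therefore planted inside the tiled interval, where the
array can see them. Planted peaks decay linearly (triangular kernel) to
zero at ±750 bp, the midpoint of the 300–1000 bp shear-fragment range,
since overlapping fragments of bounded size produce an approximately
linear fall-off of pulldown probability with distance from the site; a
Gaussian kernel is available behind a switch. Null replicates are
zero-mean Gaussian noise (sd 0.35 log2 units per replicate) with no
planted signal. A configurable fraction (default 5%) of promoter regions
links to a second, divergently transcribed gene to exercise multi-gene
mapping.

Default study scale for tests is 2,000 promoters (the real design's
~17,000 scaled down for runtime); all parameter-recovery statements in
the test suite are made at that scale.

## Motif over-representation

Candidate 8-mers are the concrete words present in target promoters
(canonicalized across strands). Presence — not occurrence count — per
promoter is the tested statistic: a one-sided hypergeometric tail on the
target/background split of the promoters containing the word. The
support filter for candidates counts presence in targets and background
*combined*; the hypergeometric test conditions on that total, so the
filter does not bias the test (filtering on target-only support would
select on the statistic being tested and destroys calibration).
Significant words are merged greedily (ascending p) into degenerate
patterns, widening at most one position per merge and allowing at most
two alternative bases per position; a motif's promoter count is the
number of target promoters containing any member word, and its p-range
spans its member words. The test statistic is isolated in one function
so binomial or Fisher variants are drop-in. Matching against the
published forkhead consensus patterns (RYMAAYA, TATTTRT, AATTTGT) is
gapless: "complete" requires every concrete variant of the motif to
contain a full instantiation of the consensus (or its reverse
complement); "partial" requires ≥6 matching positions in the best
alignment.

The sequence generator plants a random concrete instantiation of the
configured degenerate motif into a configured fraction of target and
background sequences (i.i.d. bases at 45% GC otherwise) and scrubs
chance occurrences from non-planted sequences, so the prevalence
parameters are exact presence probabilities. Real promoters are not
i.i.d. — CpG islands, repeats and compositional biases produce
correlated word statistics that this generator does not emulate — so
calibration results on synthetic sequences demonstrate the statistics,
not robustness to genomic sequence structure.

## Expression model

Signal is background-corrected by subtracting each array's mean
negative-control intensity, then variance-stabilized:
`glog2(x) = log2((x + sqrt(x² + c²))/2)`, with arrays first matched by a
robust (MAD-based) scale factor and `c` per array taken as the robust
spread of its low-intensity quartile — the additive-noise regime where
the transform must stay linear. `glog2` is monotone, ~log2 for `x ≫ c`,
and defined for the negative values background correction produces.
Genes are kept when detected (score ≥ 0.95) in at least one sample.
Outlier samples are flagged when their median inter-sample correlation
falls strictly more than 3 scaled MADs below the cohort median; more
than 25% flagged aborts with diagnostics (a batch problem, not
outliers).

Differential expression fits, per gene, ordinary least squares of
`value ~ intercept + genotype + litter` with litter as a fixed blocking
factor (embryos of one pregnancy share environment; a random-effect
treatment is not attempted at n = 11). The genotype contrast is mutant
minus wild-type; "down" means lower in the mutant. Variance moderation
(on by default) shrinks per-gene residual variances toward a pooled
prior fitted by moment matching on log-variances (the trigamma
inversion), adding the prior degrees of freedom to the t reference —
the standard small-n stabilization; the unmoderated p-value is reported
alongside. Benjamini–Hochberg q-values follow the literal step-up
definition. The permutation test enumerates exactly the genotype-label
reassignments that preserve each litter's genotype counts (the default
design — litters of 2+2, 2+2, 1+2 wild-type+mutant — gives
C(4,2)·C(4,2)·C(3,1) = 108, including the identity) and reports how many
reach the observed count of genes at p < α; above 10⁶ assignments it
switches to seeded uniform sampling.

The expression generator emits data directly on the transformed scale
(per-gene baseline ~ N(8, 1.5), per-(gene, litter) effect ~ N(0, 0.25),
noise sd 0.5, 2% DE genes at ±1.5 log2); a thin raw-scale wrapper
(2^value plus array-specific additive background) feeds the
background-correction and transform path. It does not emulate probe
cross-hybridization, detection-score correlation with intensity, or
heteroscedastic gene variances, so moderation's benefit over the
ordinary t is smaller on synthetic data than on real arrays.

## Integration and reporting

Gene identifiers are matched exactly after case normalization (no
alias resolution — same-platform lists need none). Classification is a
partition: bound + changed = direct-regulated; bound only =
direct-bound-only; changed only = indirect. The run report contains the
configuration echo, thresholds, per-stage counts, motif table, DE
summary and permutation report; it excludes timestamps, so one seed
reproduces it byte-for-byte.

## Determinism

All randomness flows from `SimConfig.seed` through fixed per-component
stream keys (design, ChIP, expression, sequences), so components are
independently reproducible and jointly deterministic. Floating-point
values are written with fixed formats; byte-identical output under a
fixed seed is a tested property.
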