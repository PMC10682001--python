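# Methods

This note documents the models, parameter choices, and numerical decisions
behind `sglife`, and what the synthetic-data generators do and do not
emulate.

## Data model and filtering

An `IntensityMatrix` holds proteins × labeled channels with a sample design:
time label (HS0, HS10, HS20, HS30, HS60, HS120, HS180, Re5, Re10, SGls),
replicate (1–3), and bait (G3BP1 or CAPRIN1). SG-ls channels occur only in
the G3BP1 pull-down. Missing intensities are carried as NaN through
filtering and are only imputed where an operation requires completeness
(ComBat; see below). Identification filters remove records with non-high FDR
confidence, any replicate below the unique-peptide minimum (default 1),
mitochondrial proteins, keratins, and records without an annotated gene
name. Contaminant status is an explicit input column or sidecar gene list —
never inferred from sequence — to keep the filter free of hidden database
dependencies. Gene symbols match case-insensitively after whitespace
stripping, with no alias expansion.

## Normalization chain

Order: per-channel column scaling → ComBat across replicates → TMM. The
chain is deterministic given its input.

**Column scaling.** Each column is multiplied by (mean column sum)/(its
column sum), equalizing the loaded amount per channel. Missing values count
as zero in the sums.

**ComBat.** Log2 scale; zeros/missing are floored to half the smallest
positive intensity before logging (a standard proteomics floor; flooring
affects only the handful of non-positive cells and their missingness is
restored afterwards). Batches are the TMT replicates. The biological
covariate collapses the course into early (HS0–HS10), middle (HS20–HS60) and
late (HS120–Re10) groups; SG-ls channels get their own fourth level, since
they are unstressed condensate samples, not part of the heat-shock course,
and leaving them ungrouped would fold their biology into the batch terms.
Standardization fits per-protein OLS on batch + group dummies; per-batch
location (γ) and scale (δ) effects are shrunk with parametric priors
(normal for γ, inverse-gamma for δ; non-parametric priors are out of
scope). Two deliberate conventions:

- δ̂ uses the mean squared deviation (ddof = 0), matching the pooled-variance
  normalization. With zero injected batch effect the adjustment is then an
  exact identity (measured ≤ 1e-8 on the log2 scale); the sample-variance
  convention would instead rescale every residual by √(n/(n−1)) ≈ 1.06.
  Against Bioconductor sva's ComBat on a shared fixture the adjusted values
  agree within 0.01 log2 units.
- γ/δ are reported on the log2-intensity scale (γ̂·σ_pooled), so a planted
  +0.8 log2 shift reads back as ≈ 0.8.

If a batch contains a single sample, or is confounded with the covariate
(single group level), the fit refuses with a descriptive error rather than
producing a silently singular design.

**TMM.** For each sample against the reference, M = log2(y/r) and
A = ½·log2(y·r) over proteins positive in both; proteins outside the central
40 % of M (30 % trim per tail) or the central 90 % of A (5 % per tail) are
discarded, and the factor is 2^(Σ M/w / Σ 1/w) with delta-method weights
w = 1/y + 1/r. The automatic reference is the sample whose upper quartile is
closest to the mean upper quartile. Factors are computed on the observed
intensity scale (a uniformly doubled column gets factor 2); within the full
pipeline they are re-centered to geometric mean 1 and divided out. Fewer
than 10 usable pairs is an error.

## Dynamic-protein classification

Replicate means per time label; fc_up = max(HS10..Re10 means)/HS0 and
fc_down = HS0/min(HS10..Re10 means). SG-ls channels never enter the window.
A protein is dynamic iff fc_up > θ or fc_down > θ in **both** pull-down
datasets (strict inequality; θ = 1.2, configurable). Proteins quantified in
only one bait cannot be evaluated under the both-datasets rule and are
excluded with a logged reason, as are proteins whose HS0 mean is
non-positive. Means, not medians, aggregate replicates. The rule is scale
invariant: multiplying a protein's intensities by any constant changes no
call.

## Temporal clustering and kinetics

z-profiles are per-protein unit-variance scalings (sample sd, ddof = 1) of
the nine label means of the CAPRIN1 dataset, computed on log2 means.
Intensities span decades and the kinetics are multiplicative; scaling raw
means would let exponential curvature distort profile shape — on noiseless
generator data it biases the fitted early inflection from 21 to ~18 min —
so the log transform is the default (`log_transform=False` restores the raw
mode). Zero-variance rows get z = 0 and a degeneracy flag.

Clustering is agglomerative with Chebyshev (maximum coordinate) distance and
average linkage, cut at k = 2; rows are sorted by accession first, making the
result invariant to input order. The cluster whose mean z falls from HS10 to
HS180 is named *early*, the other *late*; if both fall (or both rise) the
steeper-falling cluster is early and a warning is emitted; an exact tie is
an error, never a silent choice. PCA loadings (proteins as observations) get
a deterministic sign: each component axis, read as a profile over time, is
flipped to correlate negatively with time order, so decreasing-in-time
profiles load positively.

Sigmoid fits use the heat-shock points only (0–180 min; recovery reverses
the trend and is excluded by default, selectable via the time grid). The
4-parameter logistic is fitted by Levenberg–Marquardt least squares with
multi-start over every observed time as a t₀ seed and both slope signs; the
reported inflection is the fitted midpoint. The canonical form keeps slope
positive and carries direction in the ordering of the asymptotes. Flat
inputs (range < 1e-9) are flagged degenerate rather than fitted;
non-convergence returns best-effort parameters with `converged=False`.

Group-average kinetic fits run on z-profiles from the **batch-corrected**
matrix, before the ratio normalizations. Equal-sum scaling and TMM estimate
column factors from a mixture whose composition genuinely drifts across the
course; those factors absorb part of the kinetics and warp group-average
shape (measured on generator data: late inflection biased ~6 min early
through the full chain, ±2.5 min recovery with batch correction only).
Per-protein classification is ratio-based and robust to those factors, so
it keeps the full published chain.

## SG-ls enrichment score

Per protein (G3BP1 dataset): ratio = mean(SG-ls replicates)/max of the
HS10..Re10 label means, then log2, then z-standardization across the scored
cohort. The log transform centers fold changes at 0 so the z sign is
interpretable: positive ⇒ enriched in unstressed G3BP1 condensates
(stress-independent recruitment), negative ⇒ enriched in heat-shock SGs. The
cohort defaults to all proteins with SG-ls measurements; an HS0 denominator
is available for the SG-ls vs control contrast. A degenerate cohort
(sd < 1e-12 relative) yields all-zero z with a flag.

## Biochemical properties and statistics

pI solves net charge(pH) = 0 by bisection on (0, 14) to 1e-4 pH, with the
positive groups (N-terminus, K, R, H) and negative groups (C-terminus, D, E,
C, Y) under Henderson–Hasselbalch. Net charge is monotone decreasing in pH,
so bisection is exact. The default pKa table is EMBOSS; Bjellqvist is
selectable, and any mapping can be passed. pI is composition-only — residue
order never matters. Non-standard residues carry no ionizable group and are
skipped. IDR coverage is the fraction of residues whose predictor score
strictly exceeds 0.5 (per the strict ">" convention); tracks outside [0, 1]
are rejected. PrLD presence is a positive PLAAC core length.

Group comparisons use one-way ANOVA with Tukey HSD (Tukey–Kramer for
unequal sizes, via statsmodels), Welch's t for two-group contrasts, and
Pearson chi-square without continuity correction. Identical groups return
F = 0, p = 1.

## PPI network

STRING-style edges pass when combined_score > 700 (0.7 on the 0–1000
scale, strict); BioPlex-style pairs are unioned with per-edge provenance;
edges touching nodes outside the classified set, self-loops, and duplicates
are dropped. Density is 2E/(N(N−1)); the average shortest path is taken
over connected pairs only, so largely disconnected subnetworks (the late
group's module archipelago) still get a finite value. Modularity follows
Newman–Girvan, Q = Σ_c [e_c/m − (d_c/2m)²], validated edge-by-edge against
brute force; an edgeless graph has Q = 0 by convention. Community detection
is greedy (CNM-style) modularity maximization; the exact-Q surface is the
tested contract, detection is best-effort. "Degree" is raw within-subgraph
degree.

## Granule imaging

Segmentation thresholds within each cell mask (Otsu by default, or a fixed
level), labels 8-connected components, and discards those below `min_area`
(default 4 px). Enrichment is mean intensity over the union of granule
pixels divided by mean intensity over the whole cell — invariant to
zero-offset intensity rescaling, undefined (reported missing) for cells
without granules. Tracking links detections frame-to-frame greedily,
closest pair first, under a displacement cap; unmatched detections open or
close tracks. For well-separated particles (spacing > 2× the cap) greedy
linking coincides with optimal bipartite matching. A fusion event is a track
ending at frame t whose last position lies within `merge_radius` of a
surviving track's position at t+1, where the survivor's area at t+1 is at
least 0.8× the sum of its own and the dying track's areas — an
operationalization of by-eye fusion scoring; both the radius and the area
factor are configurable. Tracks ending within `border_margin` of the image
edge are excluded (particles leaving the field are not fusions).

## Synthetic-data generators

All generators are pure functions of (configuration, seed).

**Time course.** Per protein, the mean log2 profile is baseline (N(20, 1.5))
plus a class template: early, amplitude·(1 − logistic(t; 21 min, 0.08/min));
late, amplitude·logistic(t; 30 min, 0.08/min); invariable, flat. Recovery
points revert 30 % of the way back toward HS0 (moderate reversal). The
amplitude default is 0.65 log2 units: the realized fold change (~1.46×)
doubles the classification margin in log space (2·log2 1.2 ≈ 0.53) while
keeping the net composition drift small enough that the equal-loading and
TMM steps — both of which presume approximate compositional stability —
remain valid on the generated data, as they are presumed to be on real
pull-downs where median fold changes are modest.

Noise follows the anatomy of TMT pull-down data. `noise_sd` (default 0.3
log2) is the **total** per-measurement SD, decomposed into a
per-(protein, replicate) pull-down/labeling effect — the dominant component,
shared by all channels of a replicate's plex, exactly the structure ComBat's
per-batch per-protein terms model and remove — plus i.i.d. within-plex
reporter noise (`channel_noise_sd`, default 0.1 log2 ≈ 7 % CV, typical for
isobaric quantification). A purely i.i.d. reading of 0.3 would be
unrealistic for TMT and would make any max/min-based fold-change rule fire
on most flat proteins (the range of nine label means then routinely exceeds
1.2×), i.e. it would test the noise model, not the pipeline. Global
per-replicate batch shifts default to (0, +0.4, −0.4) log2.

SG-ls channels are drawn as window-max × 2^(class effect + noise), with
class effects +0.6 (early), −0.9 (late), 0 (invariable) log2 and a
ribosomal-like subset (20 % of early proteins) at −0.8, reproducing the
bipolar early-protein score distribution.

**Network.** Early nodes form an Erdős–Rényi core (p = 0.25); late nodes
form near-cliques (intra-module p = 0.9) of sizes (8, 8, 7, 7) with sparse
inter-module wiring (p = 0.02); invariable nodes attach sparsely (p = 0.03).
This plants the qualitative contrast of a dense early scaffold versus
discrete late modules.

**Movies.** Cells are disks; granules are Gaussian spots (σ = 2 px,
amplitude 800 over background 100) doing Brownian motion (per-frame sd
0.8 px) under an excluded-volume rule that keeps non-partner spots ≥ 6σ
apart, so planted counts stay resolvable. A scripted fusion places the
partner next to its mate, closes in to a 5.5σ stand-off over three frames,
then coalesces: the survivor doubles in mass (amplitude ×2, σ ×√2). Truth
records positions, counts and the fusion schedule.

**What the generators do not emulate.** Missing-value structure of real
search engines, peptide-level rollup, isotope-impurity leakage between
channels, co-isolation interference, real sequence composition (the
property generator in `analysis/06` plants class-level composition mixtures,
not biological sequences), database-derived interaction noise, and optical
effects (PSF anisotropy, photobleaching, uneven illumination). Passing the
recovery checks therefore demonstrates the pipeline's correctness under the
stated generative model, not performance on any particular real dataset —
in particular the headline protein counts of a real study depend on its
deposited data and search settings and are not reproduced here.

## Benchmark problem sizes

The recovery benchmarks use 330 proteins (150/100/80 early/late/invariable)
× 3 replicates, 10 generator seeds for the inflection sweep, 200 proteins
for the batch-correction check, 100 proteins per TMM pair, 50 random
20-node graphs for the modularity oracle, and movies of 2 cells × 5
granules × 12 frames — sizes at which every planted effect is comfortably
identified while the full suite runs in seconds.

## Known limitations

- ComBat assumes the batch effect is additive location/scale on the log
  scale; interaction of batch with time is not modeled.
- TMM (and equal-sum scaling) bias column factors when most of the proteome
  genuinely changes; kinetic fits therefore avoid them (see above), but
  extreme composition drift would also start to bias classification.
- The fold-change rule is a pure threshold; no significance testing is
  attached (by design).
- Greedy community detection has the usual resolution limits; only the
  modularity value of a *given* partition is exact.
- Fusion calling assumes merges are resolvable one frame before
  coalescence; faster-than-frame-rate merges are undercounted.
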