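# sglife

Analysis pipeline for time-resolved stress-granule (SG) proteomics: from TMT
reporter-intensity tables to a kinetic taxonomy of the SG proteome, with
companion tools for condensate-enrichment scoring, biochemical-property and
interaction-network comparisons, and live-imaging granule quantification.

Stress granules are cytoplasmic condensates that assemble within minutes of
stress and remodel continuously as stress persists. Affinity-purified SG
proteomes sampled along a heat-shock/recovery time course (HS 0–180 min,
recovery 5/10 min; two pull-down baits, G3BP1 and CAPRIN1, three TMT
replicates each) let one ask *which proteins come and go, and when*. This
package implements that analysis for anyone working with time-resolved
pull-down TMT data:

- **`quant`** — data model and TSV readers for proteins × labeled channels
  with a sample design (time label, replicate, bait), plus identification
  filters (FDR confidence, unique peptides per replicate, contaminant and
  unnamed-gene exclusion) and gene-list membership annotation.
- **`normalize`** — equal-loading column scaling; empirical-Bayes
  location/scale batch correction across TMT replicates (batches =
  replicates; covariate = coarse time groups early/middle/late so the
  kinetics of interest are not absorbed); trimmed-mean-of-M-values (TMM)
  scaling factors. For a sample–reference pair with intensities *y* and *r*,
  M = log2(y/r), A = ½·log2(y·r); after double trimming (30 % on M, 5 % on
  A) the factor is 2 to the precision-weighted mean of the retained M.
- **`dynamics`** — the fold-change rule: per protein, fc_up = max(window
  means)/mean(HS0) and fc_down = mean(HS0)/min(window means) over the
  HS10..Re10 window; *dynamic* means either ratio strictly exceeds 1.2 in
  **both** pull-down datasets, otherwise *invariable*.
- **`clustering`** — z-scoring of log2 label-mean profiles, agglomerative
  clustering (Chebyshev distance, average linkage, k = 2), PCA loadings,
  early/late naming (the cluster falling from HS10 to HS180 is early), and
  4-parameter logistic fits v(t) = lower + (upper−lower)/(1+exp(−k(t−t₀)))
  whose midpoint t₀ is the group's inflection time.
- **`sgls`** — SG-like-condensate enrichment: z-standardized
  log2(SG-ls mean / window max) per protein; positive values flag
  stress-independent recruitment into G3BP1 condensates.
- **`seqprops`** — isoelectric point by bisection on the
  Henderson–Hasselbalch net charge (EMBOSS or Bjellqvist pKa sets), IDR
  coverage (fraction of residues with predictor score > 0.5), PLAAC PrLD
  parsing, and the study's statistics (one-way ANOVA + Tukey HSD, Welch's
  t, Pearson chi-square).
- **`network`** — PPI graph assembly from STRING-style (combined score
  > 0.7) and BioPlex-style edge files restricted to the classified
  proteome; degree, density 2E/(N(N−1)), average shortest path over
  connected pairs, Newman–Girvan modularity
  Q = Σ_c [e_c/m − (d_c/2m)²], and greedy community detection.
- **`imaging`** — per-cell granule segmentation (Otsu within the cell
  mask, 8-connected components, minimum area), enrichment ratio (mean
  granule intensity / mean cell intensity), greedy nearest-neighbour
  particle linking, and fusion-event calling from track merges.
- **`simulate`** — generators for all of the above with planted ground
  truth: sigmoidal log2 kinetics (early decreasing, inflection 21 min; late
  increasing, 30 min; invariable flat), TMT-style noise anatomy, a bipolar
  SG-ls effect with a ribosomal-like early subset, planted-structure PPI
  graphs, and granule movies with scripted fusion events.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
with known truth and write their tables under `results/`:

```bash
python analysis/01_simulate_inputs.py      # two pull-down tables + truth
python analysis/02_normalize.py            # scaling -> ComBat -> TMM
python analysis/03_classify_dynamics.py    # >1.2-fold both-baits rule
python analysis/04_temporal_clusters.py    # early/late clusters + sigmoid fits
python analysis/05_sgls_scores.py          # SG-ls enrichment z-scores
python analysis/06_sequence_properties.py  # pI / IDR / RBP / PrLD comparisons
python analysis/07_ppi_network.py          # subnetwork topology
python analysis/08_granule_imaging.py      # movie quantification
```

With the default seed (7) the drivers print:

```
249 dynamic / 81 invariable (excluded: 0 G3BP1, 0 CAPRIN1)
accuracy vs planted truth: 0.991

148 early / 101 late dynamic proteins
early: decreasing sigmoid, inflection 20.21 min
late: increasing sigmoid, inflection 30.5 min
early/late accuracy vs planted truth: 1.000

median SG-ls z, early (non-ribosomal): +1.172 (n=120)
median SG-ls z, early ribosomal-like: -0.810 (n=30)
median SG-ls z, late: -1.200 (n=100)

fusion ROIs: vehicle 9/10 vs blebb 2/10 (chi-square 9.899, p = 1.65e-03)
```

Reading: of 330 simulated proteins the fold-change rule recovers the planted
dynamic/invariable split at 99 % accuracy; the two temporal clusters land on
the planted early (21 min) and late (30 min) inflections within ~1 min; SG-ls
scores separate stress-independent (early, positive median) from
stress-dependent (late, negative) recruitment, with the ribosomal-like early
subset scoring negative — the bipolar pattern; and granule-movie fusion
scoring separates the motile from the motility-suppressed condition.

The same stages are available as a CLI for external tables
(`sglife simulate|normalize|classify|cluster|sgls --help`).

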