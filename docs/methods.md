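# Methods

## The analysis

`cohortscreen` implements the statistical pipeline of a cohort-level drug
screen: donor-derived hiPSC lines are plated in 384-well plates, treated
with a drug panel (DMSO carrier as control), and profiled with Cell
Painting; a companion proteomics arm compares high- and low-responding
lines by label-free DIA mass spectrometry.  The package consumes well-level
feature tables and protein quantification matrices; image handling,
segmentation and raw MS processing are out of scope.

The stages, in pipeline order:

1. **Robust-Z normalization.**  Per plate and feature, the DMSO wells give
   a center µ (median) and spread M (median absolute deviation);
   every well is scaled as z = (x − µ) / (c · M).  With the default
   consistency constant c = 1.4826 the MAD estimates the SD under
   normality, so z reads as "number of SDs away from the DMSO phenotype";
   c = 1 gives the literal (x − µ)/M formulation and is available by flag —
   the choice rescales every downstream induction value, so it is carried
   in `RobustZTable.mad_scale`.  Features whose DMSO MAD is zero on any
   plate are flagged degenerate and excluded from retained sets.
2. **Feature reduction.**  Features with coefficient of variation
   (sample SD / |mean|) above 0.50 over the pooled DMSO wells of the run
   are removed on the raw scale (CoV on z is ill-defined: the z mean is
   ~0 by construction).  Remaining features then pass a redundancy filter:
   walking features in table order, a feature is dropped iff its |Spearman
   correlation| over all wells exceeds 0.98 with an earlier retained
   feature.  The greedy order makes the retained set reproducible; the
   filter is idempotent by construction.
3. **Induction.**  For each donor-drug pair (well-level z profiles median-
   aggregated to one vector per pair), induction is the fraction of
   retained, non-missing features with |z| > σ, default σ = 2.  Two-sided
   exceedance is used: a feature counts whether the drug pushes it up or
   down.  Missing features leave both numerator and denominator.
4. **Distance to control, correlation, stratification, embeddings.**
   Euclidean distance between each pair's profile and the same donor's
   DMSO profile, with per-drug mean/SD/CoV across donors (high CoV = high
   inter-donor variability); drug × drug Pearson (optionally Spearman)
   correlation of induction patterns across donors; responder
   stratification by induction rank with explicit k (top-k high, bottom-k
   low, ties broken lexicographically by donor id so results are
   reproducible); UMAP (n_neighbours 15, min_dist 0.01, cosine) and PCA
   projections of the filtered profiles.
5. **Cross-run reproducibility.**  For drug-donor pairs shared between two
   runs, the first Wasserstein (Earth Mover) distance between the runs'
   well-level z distributions, per feature.  EMDs are computed on
   normalized values so runs from different imaging systems are
   comparable (raw-scale option available).  DMSO-vs-DMSO EMDs give the
   reference band (95th percentile); each donor's DMSO wells are
   subsampled to the typical drug-condition well count first, so the band
   carries the same sampling noise as the drug EMDs rather than the
   smaller noise of the larger control groups.
6. **Differential proteomics.**  Proteins quantified in ≥ 1/3 of runs are
   kept (boundary inclusive); remaining missing values are imputed per run
   from a down-shifted normal N(mean − 1.8·sd, (0.3·sd)²) — the
   conventional width/downshift defaults for label-free data, both
   configurable; run medians are equalised (subtract run median, add back
   the grand median, idempotent); two-group comparisons use Student's t
   with pooled variance (Welch by flag).  The permutation FDR for a
   protein with statistic |t| is the median over group-label permutations
   of (# null |t| ≥ observed) / (# observed |t| ≥ observed), clipped to
   [0, 1] and made monotone non-decreasing along the p ranking (the
   enforcement only raises q, so it is conservative).  Permutation count
   and seed are recorded in the result.
7. **Responder-stratified differential.**  Drug-vs-DMSO fold changes and p
   values are computed separately within the high-responder lines (both
   lines' triplicate runs pooled: n = 6 vs 6) and the low-responder lines;
   proteins must be significant in *both* strata (P_high ≤ 0.05 and
   P_low ≤ 0.05), and the interaction effect log2FC_high−low =
   log2FC_high − log2FC_low must exceed 0.263 in magnitude (fold change
   ≈ 1.2).  Surviving proteins are reported as per-line fold changes,
   z-scored per protein row for heatmaps, with optional Euclidean k-means
   row clustering (fixed seed).  The dual p gate implies a protein whose
   expression shifts *only* in high responders is not callable — both
   strata must respond detectably, with different magnitude.  Exchanging
   the strata negates every interaction effect exactly.

## The synthetic screen generator

The generator emulates the statistical structure of the screen, not its
biology.  Design defaults mirror the assay: 28 donors × 52 drugs (1,456
drug-donor pairs; the two other cohort designs give 416 and 936), 871
features, 6 technical replicate wells per condition, 2 bioreplicates,
one plate per donor/bioreplicate with 16 DMSO wells, 500–667 cells per
well (6,000–8,000 per pair), 384-well row-major layout.

Structure and parameters (units: per-feature noise SDs unless stated):

- Each drug belongs to a mechanism-of-action (MoA) class; each class has a
  sparse signed signature over 15% of features with |entries| ~ U(0.5, 4.5).
  The range deliberately spans sub- and supra-threshold effects so that
  induction grows smoothly with response magnitude instead of saturating.
  Signatures mix increased and decreased features, as real fingerprints do.
- A donor's sensitivity is a per-(donor, MoA) scale ~ LogNormal(0, 0.6),
  so drugs sharing a class show correlated variable response across the
  cohort (the block structure of the induction correlation matrix).
  Responder labels derive deterministically from the magnitude quartiles
  (top quartile high, bottom low).  An optional globally-high donor
  multiplier and a cytotoxic-drug option (variance inflation + cell loss)
  are off by default.
- Raw baselines are positive (U(8, 12)) with per-feature noise scales
  LogNormal around 1 and per-plate baseline offsets (SD 0.3) as a batch
  effect.  5% of features get noise on the scale of their mean (DMSO CoV
  > 0.5, removed by the CoV filter) and 3% are near-duplicates of another
  feature (|Spearman| ≈ 1, removed by the redundancy filter).
- Well values are baseline + plate offset + magnitude · signature ·
  feature-noise-scale + noise; ground truth (signatures, magnitudes,
  labels, planted filter targets) is returned alongside the table.

The proteome generator emulates triplicate DIA runs per line and
condition: 5,895 proteins with log2 baselines ~ N(26, 2.5), run noise SD
0.2, and 150 planted drug-response proteins with |log2 effect| ~
U(1.2, 2.0) (half down-regulated) scaled by the line's responder label
(high 1.0, mid 0.65, low 0.4) — responses differ in magnitude, not in
kind, which is the hypothesis the stratified procedure tests.
Missingness is intensity-dependent (logistic in the underlying intensity,
midpoint at the 2nd percentile of baseline abundance, ~4% of entries
overall), matching protein-level DIA data with match-between-runs rather
than the heavier dropout of DDA.

What the generator does **not** emulate: spatial plate effects (edge
wells), cell-count–dependent feature noise, non-Gaussian feature
distributions, correlated feature blocks beyond exact duplicates, drug
dose-response, line-specific proteome baselines, or peptide-level
quantification noise.  Passing recovery tests therefore show the
*statistics* behave as designed under the screen's sampling structure —
not that real Cell Painting or DIA data meet these assumptions.

## Numerical and design choices

- Cell→well and well→donor-drug aggregation use the median (robust to
  outlier cells); the mean is available by flag.  The combination
  statistic is an assumption, surfaced in the API.
- CoV uses the sample (n−1) SD; features with mean exactly 0 have no
  defined CoV and are removed and reported separately.
- `emd_1d` wraps the SciPy Wasserstein distance; bulk per-feature sweeps
  use an exact vectorised quantile-segment evaluation (tested to 1e-12
  against the scalar path, and against a brute-force optimal-transport LP
  to 1e-9).  Uniform sample weights; unequal well counts are handled by
  the quantile formulation.
- Degenerate inputs raise informative errors rather than propagating
  silently: plates without DMSO wells (named), runs with < 2 observed
  log2 values, zero-variance proteins (flagged, p missing), constant
  induction vectors (correlation reported missing), zero-SD heatmap rows
  (excluded with a warning).
- All stochastic steps (generators, imputation, permutations, UMAP,
  k-means, DMSO subsampling) take explicit seeds; same seed means
  bit-identical output.

## Benchmark problem sizes

The recovery and calibration benchmarks (`cohortscreen.benchmarks`, also
driven by `scripts/acceptance.py`) run desk-scale versions of the design:
12 donors × 8 drugs × 871 features with the full 6 × 2 replicate structure
for responder recovery (20 screens); 8 donors × 10 drugs × 250 features
for the cross-run EMD comparison; 800–1,200-protein proteomes for FDR and
stratified-recovery sweeps (20 each); 5 × 384-well plates of Gaussian
control wells (300 DMSO + 84 probe wells each) for the null induction
calibration, ~10,000 feature draws.  The 300-DMSO-well plates keep the
finite-sample bias of the estimated MAD small: with ~100 control wells the
|z| > 2 tail sits ~0.005 above the asymptotic 2Φ(−2) ≈ 0.0455 because the
tail fraction is convex in the estimated spread.

## Known limitations

- The stratified procedure inherits the dual-gate blind spot described
  above (strict high-only responses are not callable).
- The permutation-FDR instantiation (median-of-ratios, no variance
  moderation / s0 = 0) is one concrete choice among several in common
  use; q values from other instantiations will differ in detail.
- The greedy Spearman filter keeps the *earlier* feature of a redundant
  pair; a different feature order yields a different (equally valid)
  retained set.
- Whether the CoV filter should run on raw or normalized values, and
  which wells it pools, is an assumption (raw scale, pooled DMSO wells).
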