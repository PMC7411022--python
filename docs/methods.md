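# Methods

## The clustering score

The per-cell score is the intensity entropy S = (1/N) Σ ρ ln ρ with
ρ = I/Ī over the N pixels of the cell's ROI and 0·ln 0 = 0. The continuous
form ∫ρ ln ρ admits several discretizations; we use the arithmetic mean of
ρ ln ρ (the 1/N factor) because an un-normalized sum grows with cell area,
while the score is meant to be intensive — two cells with the same
per-pixel intensity histogram must score identically whatever their size.
No histogram or pixel binning is applied. Properties relied on throughout
(and asserted in the test suite):

* permutation invariance — S depends only on the intensity multiset;
* gain invariance — S(cI) = S(I) for any c > 0, so multiplicative
  illumination/detector fluctuations do not move raw scores;
* bounds — 0 ≤ S ≤ ln N, equal to 0 iff intensities are constant,
  approaching ln N under single-pixel concentration. The constant case is
  short-circuited to exactly 0 to avoid spurious rounding ulps.

S is *not* invariant under additive offsets, which is why background
handling matters. The estimator is the median intensity of background
(label-0) pixels per field; subtraction is on by default and subtracted
intensities are floored at 0. The raw-intensity variant stays available
behind `background_subtract=False` because the choice is a genuine open
point: subtraction is the conservative default since an un-subtracted
offset compresses ρ toward 1 and deflates scores in proportion to
background level, breaking comparability across acquisition settings.

Masks code cells with ascending natural numbers (1..K, 0 = background, no
gaps); gapped labelings are rejected by name so upstream manual-outlining
errors surface immediately. Cells under `min_area` (default 200 px) are
dropped with a log line; border-touching cells are kept but flagged.
`segment_cells` (Otsu + components + optional watershed) exists so
synthetic fixtures run unattended — the assay itself used manual outlines,
and no claim is made that automatic segmentation matches them.

The descriptor bank around the score (intensity moments, top-decile signal
fraction, punctum statistics at a relative threshold of 0.5 with
8-connectivity and 4-px minimum area, radial signal fractions, shape) is a
documented, configurable set — not a reproduction of any specific published
descriptor list — and exists to let `rank_descriptors` (standardized
Random-Forest importances plus a t-SNE embedding) confirm that an
entropy/aggregation-type descriptor is the discriminative one between
populations that differ in clustering.

## Chip QC and normalization

Each chip carries triplicate wells of a reference line (default label
`MDA_MB231`, ≥150 pooled cells recommended, ≥10 per well required). The
gate is the Kruskal–Wallis omnibus p across the three wells: the chip
passes iff p > α (default 0.05). Dunn's tie-corrected z-tests
(Bonferroni-adjusted over the three pairs) are computed and stored as
diagnostics only; the accept/reject decision uses the single omnibus
p-value, the simplest defensible reading of a "no significant differences"
criterion. Dunn's test is implemented in `popstats` directly (mean-rank
z-statistics with the Σ(t³−t)/(12(N−1)) tie correction); the omnibus
matches R's `kruskal.test` and the pairwise values were verified against a
hand-worked example.

Normalization divides every score on an accepted chip by the arithmetic
mean of the *pooled* reference cells (concatenated triplicates, not a
mean-of-means — the two differ when well sizes differ). The pooled
reference mean is exactly 1 afterwards, and scaling all raw scores on a
chip by any c > 0 leaves every normalized score unchanged (exact
cancellation). Under the multiplicative chip-effect model the residual
inter-chip variability of a population's mean normalized score is pure
sampling noise; with 200-cell wells the acceptance script measures it below
1% CV, far inside the 5% the design aims for.

## Population statistics

* Distribution comparisons use the two-sample KS test (exact null for
  n·m ≤ 10⁴), since population differences show up in distribution *shape*
  as much as in the mean. Pairwise matrices report the fraction of pairs
  significant after multiple-testing correction (Bonferroni by default,
  any `statsmodels` method accepted).
* Colony inheritance: `colony_divergence_fraction` is the fraction of
  colony pairs with Dunn-adjusted p < α at a given day. Note an intrinsic
  property of rank-based post-hoc tests: with k fully separated groups on
  one pooled rank scale, adjacent groups differ by only N/k mean ranks, so
  the fraction saturates below 1 as k grows even for cleanly separated
  colonies; conclusions should rest on the day-10 → day-20 *drop*, which
  is what the pipeline reports.
* `bootstrap_subset_test` draws size-|colony| subsets *without replacement*
  from the unsorted baseline (matching the "random subset" null), compares
  |mean(draw) − mean(baseline)| to the observed statistic, and reports the
  add-one p-value (k+1)/(n_iter+1), which is exactly 1 when the colony is
  the baseline and never 0. Default n_iter = 10,000. A KS-distance
  statistic is available behind `statistic="ks"`. Null p-values are
  uniform (calibration asserted by simulation) and power is monotone in the
  founder offset.
* `pearson_with_split` reports the overall Pearson r between per-population
  mean scores and a phenotype, plus within-group r after splitting at a
  score threshold (default 0.4, the empirical boundary between
  low/high-clustering lines); groups contribute an r only with ≥3 members.

## Pathway enrichment score

Fixed filter order on a genes × cells matrix of E = log2(TPM+1): pathway
gene selection → exclusion of genes with mean E < 1 across all cells
(mean exactly 1 is kept; the rule is a strict "lower than") → per-cell
unweighted mean over surviving genes → discard of outlier cells with score
strictly < 3 → per-patient division by the mean score of primary-class
cells. The outlier rule is read as applying to the per-cell *pathway*
score before normalization; callers preferring the alternative reading
(the EphA2 gene's own expression) can pass that row to
`discard_low_epha2` directly. Patients are inferred from line-id suffixes
(p/m/pcr, tried longest-first so `HN120pcr` → patient HN120, class
resistant) and can be overridden with an explicit mapping. The pathway
gene list is user-supplied; the packaged list is a synthetic placeholder.

## Synthetic data

The generators encode the structure the analysis assumes, not the physics
of the assay:

* **Cell images** (256×256 px, 16-bit, cell radius 60 px, background 100
  counts, Poisson noise by default): n_puncta = 30 Gaussian puncta share
  `total_signal` = 3×10⁵ counts equally. With probability `aggregation`
  a punctum is deposited at one of ≤3 aggregate centers (width 5 px,
  centers within the inner 50% radius, mirroring the inward transport of
  clusters); otherwise it is a scattered punctum (width 2.5 px, uniform
  over the cell). Every punctum is renormalized over the mask, so
  integrated foreground is independent of aggregation — aggregation
  redistributes signal, never adds it — and the expected score rises
  monotonically with the parameter. The original imagery's noise and
  density figures are not published, so these defaults are explicit
  stand-ins, all configurable.
* **Chips**: the chip effect is a single multiplicative gain on per-cell
  *scores* (not raw intensities — the score's gain invariance would erase
  an intensity-level effect), consistent with proportional day-to-day
  detection fluctuations that reference normalization is designed to
  cancel. The fast score-level path resamples from an image-calibrated
  score pool and agrees with the image-level path in distribution by
  construction; batches share one calibration.
* **Colonies**: day-10 scores are founder-centered with sd 0.08 (default);
  day-20 scores mix colony-centered and fresh baseline draws with weight
  w ∈ [0, 1] (0 = perfect inheritance, 1 = full reversion), reproducing
  the narrow-then-converging signature, including rising CVs.
* **Expression**: pathway genes get line-specific Gaussian means in E
  units, other genes a shared mean (2.0), dispersion 0.5, dropout 0.1.

What passing tests on these data do and do not show: they verify the
mathematics and plumbing of the pipeline — exactness of the score,
cancellation of multiplicative batch effects, calibration of every test's
type-I error, the qualitative inheritance signature — under the generative
assumptions above. They do not validate biological claims: real cells are
not disks, real backgrounds are not flat, real chip effects need not be
purely multiplicative, and real expression is not Gaussian with uniform
dropout. Analyses of real data should treat the defaults as starting
points.

## Problem sizes

Simulation-backed tests and the acceptance script use deliberately modest
sizes chosen to make the checked effects decisive at desk scale: 50-cell
score pools for ordering/monotonicity checks, a 6-chip batch with 200-cell
wells and 150-cell calibration pools for the normalization study, 1,000
replicates for type-I-error calibration, 300×1,999 draws for bootstrap
calibration, and 40-cell colonies for the inheritance pipeline. All
randomness flows from explicit integer seeds; every generator is
bit-reproducible under a fixed seed.

## Known limitations

* Automatic segmentation is a convenience, unvalidated against manual
  outlines.
* Dunn post-hoc adjacency power saturates with many groups (see above).
* The descriptor bank is a methodological stand-in, not a published
  descriptor list.
* The score-level chip path reuses one empirical pool per population;
  it captures the score distribution but not per-image covariates
  (area, background) of the image-level path.
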