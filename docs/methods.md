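# Methods

## The problem

A self-resolving immune response — an infection cleared, a vaccine response
that subsides — carries gene expression away from baseline and back again.
Two genes whose induction pulses are offset by roughly a quarter of the
sampled period trace a *loop* when plotted against each other, and a loop is
a usable map: a sample's position around it encodes how far along the
inflammation→resolution trajectory that sample sits. `phaseloop` automates
finding such phase-shifted gene pairs in longitudinal expression data and
using the resulting loop to stage new samples.

## Pipeline

Given a genes × samples log2 matrix with `(individual, time)` metadata:

1. **Impute.** Any individual missing a grid time receives, per gene, the
   median value across the individuals observed at that time.  Imputation
   runs first because baseline centering needs a time-0 value, which may
   itself be imputed.
2. **Center to baseline.** Each individual's time-0 value (per gene) is
   subtracted from that individual's whole series.  This also removes stable
   per-donor offsets.  Centering is idempotent.
3. **Composite profile.** Per gene and time point, the median across
   individuals, re-centered so the baseline column is exactly zero.
4. **Filter.** Keep the `ceil(top_fraction × n_genes)` genes with the
   largest temporal dispersion of the centered composite.  Dispersion is the
   population standard deviation over the T time points by default (max–min
   range available via config).  The ceiling convention matters: at the
   default `top_fraction = 0.005` it keeps 95 of 18859 and 91 of 18197
   genes, where floor or round would keep one fewer.  Ties at the cutoff
   break lexicographically.  We filter on *centered* values; filtering raw
   values differs only by the (removed) per-gene baseline.
5. **SAX.** Each filtered gene's composite series is z-normalized
   (population moments; constant series are rejected — their symbols would
   be undefined) and discretised one symbol per time point into the
   equiprobable regions of the standard normal, lower-inclusive
   (`[b_{i-1}, b_i)`).  The default alphabet has 4 symbols (quartile
   breakpoints ±0.6745, 0): small enough to be robust on grids of ~9
   points, configurable from 2 to 20.  Piecewise aggregate approximation
   (equal-length segment means) is available behind `word_length` for longer
   series but is off by default because T is small.
6. **Search pattern.** A word shifted right by `floor(T/4)` symbols — the
   quarter-period lag that makes two pulses trace a circle — with the
   vacated positions as wildcards and the overhang discarded.  Floor
   rounding maps T = 9 to a 2-symbol shift.  No wrap-around: the time course
   is not periodic, and wrapping would fabricate a return-to-start the data
   cannot support.
7. **Pair search.** For every ordered pair (lead, lag), the lag gene's word
   is compared with the lead gene's pattern by Hamming distance over the
   `T − shift` non-wildcard positions.  The pair is a loop candidate when
   the distance is at most `max_distance`.  The default threshold is 0
   (exact match); 1 is the recommended setting for noisy data, where the
   expected number of noise-flipped symbols per compared word is below one
   half (see noise analysis below).  Matching is directional — the lead's
   shifted pattern against the lag's word encodes "lead peaks first".
8. **Polar scoring.** The pair's samples form a 2-D point cloud; both axes
   are range-normalized to [0, 1], and the loop center is the point
   minimizing the population variance of sample radii, searched on a
   101 × 101 grid over the bounding box with one 10× finer refinement pass
   around the best cell (ties to the smallest (x, y)).  Angles are measured
   counterclockwise from the positive x-axis and re-zeroed to the circular
   mean angle of the baseline samples.  Unwrapped monotonically in time-rank
   order (a sample is shifted by full turns until it lies within 180° of the
   previous rank's mean), the angle's Pearson correlation with the *ordinal*
   time rank scores how faithfully the loop encodes time; raw hours would
   let a late sample (e.g. 48 h on a 0–48 h grid) dominate the fit.
9. **Staging (KNN).** A withheld sample is placed in the pair's raw 2-gene
   plane and labeled by majority vote of its K = 3 nearest training samples
   (Euclidean).  Vote ties go to the single nearest neighbor; distance ties
   to training input order — deterministic and standard.  Polar coordinates
   are for scoring and visualization; prediction uses the raw plane.
   Labels may first pass through a *stage map* collapsing biologically
   interchangeable times (e.g. vaccination days 0/14/28 → "base",
   3/7/10 → "early"/"middle"/"late"); `YF17D_STAGE_MAP` ships as the
   default for that design, and times can be excluded (e.g. day 60, after
   which such data add no trajectory information).

Evaluation utilities: confusion matrix + accuracy (`evaluate`),
leave-one-individual-out cross-validation (`loocv`), Gaussian noise
sensitivity (per-gene, per-time SD estimated from training data, added to
test coordinates — added rather than substituted, the conservative reading),
and a null comparison of candidate-pair versus randomly drawn non-candidate
gene-pair holdout accuracies by two-sample Kolmogorov–Smirnov test
(asymptotic p-value by default, exact behind a flag).

## Synthetic data

The generator emulates the structure of a longitudinal immune time course:

- **Grid**: 9 points at 0, 2, 2.5, 3, 3.5, 4, 14, 24, 48 hours — a dense
  early phase and sparse resolution tail, deliberately uneven.
- **Planted pairs** (default 3): the lead gene follows a raised-cosine pulse
  on the *time-rank* axis (grids are uneven and every downstream step is
  per-sample or ordinal anyway) of width `w = T − 1 − lag` ranks and
  amplitude 4 log2 units (16-fold induction, typical of strongly induced
  inflammatory genes); the lag gene is the same pulse delayed by
  `round(lag_fraction × T)` ranks (default quarter period, 2 ranks at
  T = 9).  The width choice is deliberate: lead and lag series then contain
  the same multiset of values, so z-normalization maps both to identical
  symbols and a noise-free planted pair always matches its search pattern at
  distance 0, for any seed.
- **Background** (default 500 genes): baseline 0 plus noise only.
- **Noise**: i.i.d. Gaussian per value (default SD 0.2, i.e. 5% of the
  pulse amplitude) plus a per-gene, per-individual offset (SD 0.2) modelling
  stable between-donor differences — the simplest structure that makes
  leave-one-individual-out non-trivial.  Offsets cancel exactly under
  baseline centering; i.i.d. noise does not.
- **Missingness**: a configurable fraction of (individual, time) samples is
  deleted uniformly at random, never emptying a time point.

Noise analysis behind the `max_distance = 1` recommendation: after
centering, a composite-median value carries noise SD ≈ √2·1.25·σ/√n over n
individuals; at σ = 0.1 × amplitude and n = 12 this is ≈ 0.14 in z-units,
against a minimum margin of ≈ 0.22σ between the pulse's z-scores and the
nearest quartile breakpoint.  That puts the expected number of flipped
symbols per compared word pair around 0.4 — large enough that demanding an
exact match occasionally loses a pair, small enough that one allowed
mismatch recovers essentially all of them without admitting background
pairs.

What the simulation does *not* model: probe- or batch-level artifacts,
heteroskedastic (intensity-dependent) microarray noise, gene–gene
correlation in the background, drop-out structure tied to biology, or
drifting baselines.  Passing tests therefore demonstrate the machinery —
that planted quarter-period structure is found, staged, and separated from
a random-pair null at realistic noise — not that any particular real
dataset contains such pairs.

## Numerical choices and degenerate inputs

- Medians use the standard sample convention (even count → mean of the two
  central values).
- Standard deviations and radius variances use the population convention
  (irrelevant to argmins/rankings; fixed for reproducibility).
- Grid center search is exact only when the true center lies on the grid
  (e.g. a circle sampled symmetrically so the bounding box is centered);
  otherwise accuracy is one refined cell, ~10⁻³ of the data range.
- Collinear or identical point clouds have no loop and are rejected; a
  sample exactly at the center gets radius 0 and the previous sample's
  angle, with a warning.
- Probes mapping to multiple genes are unsupported input (the mapping is
  taken as single-valued); unmapped probes are dropped and counted in the
  log.
- Grids shorter than 6 time points warn but run — too short to resolve a
  full rise-and-return for two offset variables, which needs at least four
  well-placed samples.
- All randomness (simulation, splits, noise replicates, random pairs) flows
  from explicit integer seeds; identical configuration and seed give
  byte-identical outputs.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the pipeline at the
generator's study conditions — 12 individuals × 9 time points, 500
background genes, 3 planted pairs (5 for the null comparison, against 50
random pairs) — and check KNN against an exhaustive-distance oracle on 200
random instances of up to 50 points.  These sizes exercise every code path
at full fidelity while keeping a complete run under a few seconds.

## Known limitations

- The phase-shift is fixed at a quarter period by default; pairs offset by
  other fractions trace ellipses the pattern search will miss unless
  `shift_symbols` is changed.
- With a 4-symbol alphabet and ~7 compared positions, unrelated genes can
  collide by chance once the candidate gene set grows; the holdout-accuracy
  ranking, not the match distance, is the final arbiter.
- Directional matching reports (lead, lag) order; a biologically reversed
  pair appears with the roles swapped, and recovery scoring accepts either
  orientation.
- The loop map assumes a *shared* trajectory across individuals; donors
  traversing the loop at different rates blur angle–time correlation, which
  is visible as a depressed ρ rather than flagged explicitly.
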