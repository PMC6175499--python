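# phaseloop

Loops in longitudinal gene-expression data as maps of an
inflammation→resolution trajectory.

When an immune response resolves, induced genes rise and return to
baseline in sequential waves.  Two genes whose pulses are offset by about a
quarter of the sampled period trace a **loop** when plotted against each
other, and that loop separates the stages of the response: a new sample's
position around it tells you how far along the perturbation it is.
`phaseloop` is for researchers with longitudinal (bulk or single-cell
pseudobulk) expression cohorts who want to find such phase-shifted gene
pairs automatically and use them to stage withheld samples.

## Method in brief

For a genes × samples log2 matrix with per-sample `(individual, time)`
metadata, the pipeline:

1. imputes missing time points with cross-individual medians and rescales
   every individual's series to its time-0 baseline;
2. builds a composite median profile per gene over the T time points and
   keeps the top fraction (default 0.5%, ceiling convention) by standard
   deviation across time;
3. converts each kept gene's profile to a **SAX word** (z-normalize, one
   symbol per time point from the equiprobable regions of N(0,1), 4-letter
   alphabet by default) and derives a **search pattern** by shifting the
   word right by ⌊T/4⌋ symbols — the quarter-period (90°) lag at which two
   pulses trace a circle;
4. emits an ordered candidate pair (lead, lag) whenever the lag gene's word
   matches the lead gene's pattern within a Hamming-distance threshold
   (0 by default, 1 recommended for noisy data);
5. scores each candidate's loop geometry by polar transformation — center =
   minimum-radius-variance grid point, angles anchored at the baseline
   samples — and by the Pearson correlation ρ of unwrapped angle vs ordinal
   time rank;
6. stages withheld samples with K-nearest neighbors (K = 3, Euclidean) in
   the pair's raw 2-gene plane, optionally through a stage map that merges
   interchangeable times (e.g. vaccination days 0/14/28 → "base"),
   and ranks candidates by holdout accuracy.

Evaluation helpers cover confusion matrices, leave-one-individual-out
cross-validation, Gaussian noise sensitivity, and a Kolmogorov–Smirnov
comparison against randomly drawn gene pairs.  A seeded synthetic-data
generator plants quarter-period pulse pairs in a realistic 9-point uneven
time grid so the whole pipeline is testable without any downloads.
See `docs/methods.md` for the full model and its assumptions.

## Worked example

```python
from phaseloop import *

cfg = SimulationConfig(seed=11, n_planted_pairs=1, n_background_genes=50,
                       noise_sd=0.1)
ds, truth = generate(cfg)                      # 52 genes x 108 samples
prep = center_to_baseline(impute_missing_timepoints(ds))
train, test = split_stratified_by_time(prep, 0.5, seed=11)

prof = composite_median_profile(train)
genes = filter_top_dynamic(prof, FilterConfig(top_fraction=0.05))
words = [to_sax(prof.gene_profile(g), gene=g) for g in genes]
cands = find_phase_shifted_pairs(words)
print([(c.lead_gene, c.lag_gene, c.match_distance) for c in cands])

loop = fit_polar_loop(train, "LEAD_00", "LAG_00")
print(f"angle-time rho: {loop.angle_time_rho:.3f}")

smap = synthetic_stage_map(cfg.times)          # first/last time -> 'base'
res = predict_pair(train, test, ("LEAD_00", "LAG_00"), stage_map=smap)
print(f"holdout stage accuracy: {res.accuracy:.3f}")
```

prints

```
[('LEAD_00', 'LAG_00', 0)]
angle-time rho: 0.996
holdout stage accuracy: 1.000
```

The planted pair is the only candidate: its lead word `abdddbaaa` shifted
by two symbols (`??abdddba`) exactly matches the lag gene's word
`aaabdddba`.  The fitted loop's angle tracks time almost perfectly
(ρ = 0.996), and all 54 withheld samples are staged correctly
(`res.confusion` holds the 8-stage confusion matrix).

The same workflow is available from the shell:

```sh
phaseloop simulate --seed 11 --planted-pairs 1 --background-genes 50 \
    --noise-sd 0.1 --out sim.tsv --truth-out truth.tsv
phaseloop find-loops --input sim.tsv --top-fraction 0.05 \
    --split-fraction 0.5 --seed 11 --out loops.tsv
phaseloop predict --train sim.tsv --test sim.tsv \
    --lead LEAD_00 --lag LAG_00 --out report.tsv
phaseloop loocv --input sim.tsv --lead LEAD_00 --lag LAG_00 --out cv.tsv
phaseloop null-test --input sim.tsv --top-fraction 0.2 --n-random 15 \
    --seed 2 --out null.json
```

Input files use a plain TSV dialect (`gene<TAB>D1:0<TAB>D1:2.5 ...` with
`individual:time` column headers, log2 values); a reader for local GEO
series-matrix + platform-annotation files is included
(`read_geo_series_matrix`, no network access).

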