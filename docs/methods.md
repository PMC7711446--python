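# Methods

## Problem setting

Actigraphy monitoring of bipolar-disorder patients produces long,
non-stationary series of 30-s activity counts (2880 per day), annotated
with a mood state: depression (`dep`), mania (`man`) or remission
(`rem`). The analysis implemented here asks whether a single complexity
feature per record — slope entropy of the record's main activity epoch —
separates the states pairwise, and quantifies that separation with
threshold classification, rank statistics and bootstrap leave-one-out
(LOO) validation.

## Preprocessing

Raw records are highly artefactual: sleep and off-wrist periods are long
stretches of near-zero counts that would dominate any entropy estimate.
The extraction stage therefore:

1. zero-fills missing samples (absence of measured movement), rejecting
   records with more than 5 % missing — the inclusion rule of the
   measurement regime;
2. smooths with a centred moving average, window 250 samples (125 min);
   edge windows truncate to the available samples and divide by the
   actual count, so constants are fixed points of the filter. For even
   windows the extra sample sits on the right;
3. thresholds the *smoothed* signal at its own mean, strictly (`>`), so a
   constant record yields no epochs rather than one full-length epoch
   (an inclusive comparison is available via
   `PreprocessConfig(threshold_inclusive=True)`);
4. reads the surviving maximal runs back from the **raw** record (the
   smoothed values are only a detector), discarding runs shorter than
   1000 samples;
5. selects a representative: the longest run (ties: earliest start), all
   runs ≥ N (`all_ge_min`, used by the length sweep), or the longest run
   truncated to its first 1000 samples (`fixed_length`);
6. z-normalises the representative to zero mean and unit *population*
   (1/N) standard deviation — the epoch is treated as the complete
   object, not a sample from a longer one.

Records with no qualifying run raise a named rejection that the pipeline
aggregates instead of failing; class counts are reported at every stage.
Two structural invariants follow and are tested: epoch values always come
from the raw record (a planted one-sample spike survives), and the whole
pipeline is invariant to positive rescaling of the raw counts (the
threshold scales with the signal; z-normalisation removes scale).

## Entropy measures

**Slope entropy** (the primary feature). Differences `d` map to symbols
via `γ > δ > 0`: `+2` for `d > γ`, `+1` for `δ < d ≤ γ`, `0` for
`|d| ≤ δ`, `−1` for `−γ ≤ d < −δ`, `−2` for `d < −γ`. The printed form
of the rule leaves `d = −δ` ambiguous; this implementation resolves the
boundary symmetrically (`0` iff `|d| ≤ δ`), which also makes the measure
exactly invariant under sign flip and translation of the series (both
property-tested). A window of `m` samples yields the pattern of its
`m − 1` symbols; the value is the Shannon entropy, in nats, of the
relative pattern frequencies over the patterns actually observed — never
over the full `5^(m−1)` alphabet. Working configuration: `m = 6`,
`γ = 0.94`, `δ = 10⁻³`, with `γ` grids (0.10–0.90 step 0.10; 0.80–0.95
step 0.01) available through `gamma_grid_search`. Per-dataset reporting
normalises by the dataset maximum, mapping values to (0, 1].

**Comparators.** Sample entropy (`−ln(A/B)`, Chebyshev distance,
self-matches excluded, both template counts over the `N − m` windows
that admit an `(m+1)`-extension; undefined when either count is zero);
permutation entropy (ordinal patterns, delay 1 by default, ties ranked
by earlier index — deterministic and reproducible, unlike jitter
tie-breaking); weighted permutation entropy (window-variance weights);
bubble entropy (Rényi-2 entropy of bubble-sort swap counts at window
sizes `m` and `m+1`, normalised by `ln((m+1)/(m−1))`). Each measure is
verified exactly against an explicit-loop brute-force oracle on random
series up to length 200, including tied-value series.

## Classification and statistics

Each epoch's entropy is its score. The ROC curve sweeps all distinct
scores (plus a sentinel endpoint); orientation is auto-detected as the
direction with AUC ≥ 0.5, since which class scores higher varies by pair.
The operating threshold is the ROC point nearest (0, 1) in Euclidean
distance (ties: higher TPR, then lower threshold); the returned threshold
is the least extreme score still classified positive, and held-out scores
are classified by `score ≥ threshold` (or `≤` under the flipped
orientation). From the confusion matrix: Se = TP/(TP+FN),
Sp = TN/(TN+FP), Acc = (TP+TN)/total, and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) with the common
degenerate-denominator-to-zero convention so one-class predictions stay
defined.

Group differences use the two-sided Wilcoxon rank-sum (Mann–Whitney)
test — the applicable test for unpaired groups of unequal size. For
pooled sizes ≤ 12 the p-value is computed by full enumeration of group
assignments with midranks (exact under ties); larger samples use the
tie-corrected normal approximation.

The bootstrap LOO draws, per realisation, one record per class uniformly
at random (with replacement across realisations), re-derives the
threshold on the remainder, and scores the held-out pair (accuracy
∈ {0, ½, 1}); 1000 realisations by default, reported as mean ± SD. Note
that realisations of one dataset share its quirks: the mean's true
uncertainty includes a dataset-level component, which the null-behaviour
test accounts for by averaging over independent null datasets. Because
the trained threshold is itself a training score, a held-out record more
extreme than its whole training class can be missed even on separable
data — the reason LOO accuracy sits slightly below resubstitution
accuracy.

## Synthetic cohorts

No public dataset of mood-annotated actigraphy at this regime exists, so
experiments run on a seeded generator that emulates what the analysis
relies on — not raw accelerometry physics. One record is

```
x[t] = scale · env[t] · max(0, 1 + 0.35 u[t]) · exp(0.05 z[t])
```

with `env` a square-wave circadian envelope (each day opens with a rest
block, fraction 1/3, at 2 % of the awake scale), `u` a unit-variance
AR(1) process with lag-one autocorrelation `φ = 1 − complexity`, and a
mild multiplicative log-normal noise. On a z-normalised epoch the slope
SD is ≈ √(2(1−φ)), so `complexity` directly widens the slope-symbol
distribution and raises slope entropy — the planted effect. Missing
samples are represented by an explicit mask (never sentinels) at up to
5 %, injected uniformly at random.

Per-state complexity presets are dep = 0.30, rem = 0.42, man = 0.60,
with a per-record jitter of SD 0.10 (each record draws its own level
around the state centre). The presets and jitter were calibrated once,
by simulation, so that (i) the class-mean normalised slope-entropy gaps
are a few hundredths, (ii) the ordering dep < rem < man is recovered
reliably at the default 44/16/137 cohort composition, and (iii) the
classes genuinely overlap, putting pair accuracies in a non-trivial
0.7–0.95 regime. Without between-record jitter the classes separate
perfectly and every comparison saturates at accuracy 1.

What the generator does **not** emulate: weekly/seasonal structure,
medication and hospitalisation effects, device artefacts, heavy-tailed
count distributions, or within-day behavioural routines. Passing tests
therefore demonstrate that the pipeline recovers a planted complexity
ordering under realistic sampling and missingness — not that the
clinical effect itself is reproduced.

## Experiment templates and problem sizes

`run_experiment` composes generate/load → dedup → preprocess → entropy →
per-pair evaluation into a deterministic, config-hashed report;
`length_sweep_experiment` repeats it over a grid of minimum epoch
lengths with the `all_ge_min` strategy (epoch counts shrink as N grows);
deduplication policies keep one episode per (subject, state) or drop
single-state subjects with a configurable exempt class (the smallest
class is exempted by default, as thinning it further would empty it).

Test and replicate studies use 2-day records and cohorts of a few dozen
records per class: epoch extraction, the planted ordering and the
classification machinery are insensitive to record length beyond the
first day (the representative epoch is a single awake block either way),
and these sizes keep the full suite fast. The ordering/top-accuracy
replicate study uses the full 44/16/137 composition at 2-day length.

## Known limitations

- The generator's AR(1)-with-envelope model is one of many signal models
  consistent with the measurement regime; conclusions about real
  actigraphy require real records (the CSV reader accepts them in the
  same tabular dialect).
- Slope entropy's natural-log base is a convention; values in bits scale
  by 1/ln 2 and the classification is unaffected (thresholds scale too).
- The LOO draws held-out records independently per realisation; it is a
  bootstrap estimate, not exhaustive leave-one-out.
- Multi-class (three-way) classification and multiple-testing correction
  across grid cells are out of scope.
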