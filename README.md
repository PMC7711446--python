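# slopact

Slope-entropy analysis of actigraphy records for mood-state classification
in bipolar disorder (BD).

Wrist actigraphs record gross motor activity as non-negative counts per
30-s epoch (2880 samples per day). The three BD mood states — depression
(`dep`), mania (`man`) and remission (`rem`) — are hypothesised to differ
in the *irregularity* of daytime activity, and a single entropy value per
record turns out to be a usable classification feature. `slopact`
implements that analysis end to end for researchers working with
actigraphy or similar rest–activity time series:

1. **Preprocessing** — smooth the record with a 250-sample moving
   average, threshold at the mean of the smoothed signal, keep the
   maximal above-threshold runs (≥ 1000 samples) read back from the *raw*
   record, select a representative (longest / all / fixed-length-1000),
   and z-normalise it (zero mean, unit SD).
2. **Entropy features** — Slope Entropy (the primary feature) plus four
   comparators under one contract: Sample Entropy, Permutation Entropy,
   Weighted Permutation Entropy and Bubble Entropy.
3. **Evaluation** — a score threshold from the ROC point nearest
   (FPR, TPR) = (0, 1); sensitivity, specificity, accuracy and the
   Matthews correlation coefficient (MCC); a two-sided Wilcoxon rank-sum
   test per class pair; and a 1000-realisation bootstrap leave-one-out
   (LOO) validation that repeatedly holds out one record per class.
4. **Synthetic cohorts** — a seeded generator producing cohorts (default
   44 dep / 16 man / 137 rem records of 14 days) with circadian
   rest–activity alternation, up to 5 % missing samples, and a planted
   per-state complexity ordering dep < rem < man, so the whole pipeline
   is reproducible without any clinical data.

## The statistic at the core

Slope Entropy (SlopEn) symbolises consecutive differences
`d = x[j+1] − x[j]` with two thresholds `γ > δ > 0`:

```
+2 if d > γ        +1 if δ < d ≤ γ       0 if |d| ≤ δ
−1 if −γ ≤ d < −δ  −2 if d < −γ
```

Each window of `m` samples contributes the pattern of its `m − 1`
symbols; SlopEn is the Shannon entropy (nats) of the relative frequencies
of the distinct patterns observed over all `N − m + 1` windows. The
working configuration throughout is `m = 6`, `γ = 0.94`, `δ = 10⁻³` on
z-normalised epochs.

## Worked example

```python
import slopact as sp
from slopact import MoodState

spec = sp.CohortSpec(
    counts={MoodState.DEP: 20, MoodState.MAN: 10, MoodState.REM: 30},
    configs={s: sp.GeneratorConfig(n_days=2) for s in MoodState})
cfg = sp.ExperimentConfig(cohort=spec, seed=1, run_loo=True)
print(sp.run_experiment(cfg).render())
```

prints (abridged):

```
Stage counts: records_in=60, records_dedup=60, records_rejected=0, epochs=60

Per-class entropy summaries (dataset-max normalised):
                            method state  n  mean_norm  sd_norm
slopen(delta=0.001,gamma=0.94,m=6)   dep 20   0.910357 0.057804
slopen(delta=0.001,gamma=0.94,m=6)   man 10   0.990903 0.005301
slopen(delta=0.001,gamma=0.94,m=6)   rem 30   0.960400 0.023932

Classification results:
   pair    se       sp      acc      mcc  p_value  loo_mean_acc
dep-man 0.90  1.000000 0.933333 0.866025 0.000169        0.9140
dep-rem 0.85  0.600000 0.700000 0.446663 0.001941        0.6005
man-rem 0.90  0.866667 0.875000 0.708784 0.000089        0.8400
```

The class-mean normalised SlopEn recovers the planted complexity ordering
(dep 0.91 < rem 0.96 < man 0.99); the dep–man pair separates best
(accuracy 0.93, MCC 0.87, rank-sum p ≈ 2·10⁻⁴), and the bootstrap LOO
accuracy sits slightly below the full-data accuracy, as expected when the
threshold is trained without the held-out records.

The same stages are available from a shell:

```sh
slopact generate --n-dep 20 --n-man 10 --n-rem 30 --days 2 --seed 1 --out records.csv
slopact preprocess --in records.csv --out epochs.csv
slopact entropy --in epochs.csv --method slopen --out entropies.csv
slopact experiment run --config cfg.yaml --out results/
```

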