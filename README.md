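# qct — windowed complexity of beat-to-beat haemodynamics for tilt-test outcome prediction

Head-up tilt testing (HUTT) provokes vasovagal (pre)syncope to diagnose
reflex syncope, but the provoked faint is unpleasant and potentially
reinforcing, so a marker that predicts the outcome *before* the collapse is
clinically valuable. Heart rate (HR) and blood pressure drop only seconds
before the faint; the hypothesis implemented here is that the *network* of
interdependencies among many beat-to-beat haemodynamic channels reorganises
earlier, and that a single windowed statistic of that network — a
quantitative complexity measure — separates impending fainters from
non-fainters minutes in advance.

This package is for physiologists and methodologists who want a fully
tested, reproducible implementation of that analysis: a synthetic cohort
generator (real beat-to-beat impedance-cardiography recordings of this kind
are not publicly deposited), the dependency detector, the complexity
statistic, and the complete statistical evaluation.

## The statistic

Each subject contributes twelve beat-sampled channels (HR; systolic,
diastolic and pulse pressure; pre-ejection period; ejection time; stroke
volume; cardiac output; Heather index; vascular resistance; arterial
compliance; thoracic fluid content — mean arterial pressure is excluded as
an algebraic derivative, MAP = DBP + PP/3). In a moving window of 100 beats:

1. **Generalised correlation.** Every channel pair's scatter plot is
   rank-binned into a 10×10 image whose pixel intensity is the point count.
   Dependence of any shape concentrates mass and lowers the image's Shannon
   entropy; the pair is declared *structured* when its entropy falls below
   the 5% quantile of a permutation null. This detects non-linear and
   non-monotone coupling that Pearson correlation misses, and is invariant
   to monotone transforms and outliers.
2. **Matrices.** S is the 12×12 binary adjacency matrix of structured
   pairs; E holds each pair's plug-in mutual information in bits.
3. **Complexity.** C = f(S∘E), where ∘ is the Hadamard (entrywise) product
   and f the spectral norm. S∘E is symmetric and non-negative, so C is its
   largest eigenvalue (Perron root), in bits. C = 0 for a fully independent
   system and grows with both the number and the strength of couplings.

The evaluation anchors every subject at their test termination time and
compares complexity, HR and MAP at 300…30 s before termination:
normality-gated group tests (Student t / Mann–Whitney U), empirical ROC
curves with DeLong 95% CIs and paired DeLong tests, and Youden-optimal plus
sensitivity/specificity-constrained cutoffs.

## Worked example

```bash
python examples/04_full_study.py
```

simulates an 18/9 cohort and evaluates it end to end; on this machine it
prints

```
AUC by time before termination (higher value -> predicts syncope):
variable     complexity_bits  hr_bpm  map_mmhg
timepoint_s
30.0                   1.000   0.599     0.488
60.0                   1.000   0.543     0.432
120.0                  0.617   0.568     0.414
180.0                  0.611   0.549     0.481
240.0                  0.426   0.506     0.469
300.0                  0.414   0.531     0.438
```

Reading: five minutes before termination complexity carries no signal
(AUC ≈ 0.5 — the pre-syncope coupling has not begun), while in the final
minute it separates the groups almost perfectly; MAP never discriminates,
and HR hovers near chance because the ROC direction is fixed a priori
(higher → syncope) and control tachycardia pulls it the other way. The
cutoff table in the same output gives the complexity thresholds (bits)
achieving the Youden optimum and the sensitivity > 80% constraint per time
point. The other examples demonstrate the cohort generator
(`01_simulate_cohort.py`), the dependency image on a U-shaped relation that
Pearson correlation misses (`02_dependency_image.py`), and a single
subject's complexity trajectory (`03_complexity_series.py`).

A thin CLI mirrors the pipeline stages:

```bash
qct simulate --n-syncope 54 --n-control 27 --seed 1 --out cohort/
qct complexity --beats cohort/syn001.csv --out syn001_c.csv
qct run-all --n-syncope 54 --n-control 27 --seed 1 --stride 5 --out results/
```

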