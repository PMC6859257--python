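# pairscreen

Unbiased all-pairs regression screening for prognostic-marker discovery
in longitudinal, multi-study preclinical data.

## The problem

Preclinical studies accumulate far more measurements than any single
hypothesis uses.  Pooled across studies, such data — here the archetype
is a rat endotoxemia ("septic") model: dozens of vital, blood and
plasma parameters measured at a handful of time points in treated and
control animals, with survival recorded — hide relationships nobody
thought to test.  `pairscreen` makes *every* ordered pair of parameters
its own hypothesis: at every time point, in every subject population,
it fits six functional prototypes to each pair and asks how well any of
them explains the data.  Pairs whose coupling differs between survivors
and non-survivors, or appears and disappears as disease progresses, are
candidate prognostic markers.

## The method

For a parameter pair (x, y) at one time point in one population, only
subjects with both values present enter two "clean vectors" (no
imputation).  Six curve families are fitted:

| family      | f(x)                                              | free parameters |
|-------------|---------------------------------------------------|-----------------|
| linear      | a·x + b                                           | 2 |
| sigmoid     | a + (b−a)·( b·c / (c + (b−c)·e^(−d·b·(x−e)) ) )   | 5 |
| exponential | a·e^(b·x+c) + d                                   | 4 |
| quadratic   | a·x² + b·x + c                                    | 3 |
| cubic       | a·x³ + b·x² + c·x + d                             | 4 |
| logarithmic | a + ln(b·x + c) + d                               | 4 |

each by minimizing the normalized sum of squared errors

    sse_ratio = Σᵢ (f(xᵢ) − yᵢ)² / Σᵢ (ȳ − yᵢ)²,

with goodness of fit **GoF = 1 − sse_ratio** (an R² analogue that is
also meaningful for the non-linear families).  Because the non-linear
objectives are multimodal, each fit runs a Monte-Carlo multistart of
downhill-simplex (Nelder–Mead) minimizations from data-driven start
boxes — derivative-free, so domain violations can simply be scored +∞.
All restarts of all pairs in a slice advance through one vectorized
simplex loop, which is what makes half a million regressions tractable
on a desk machine.

The subject populations come from crossing two group classifiers,
treatment × survival: I treated survivors, II treated non-survivors,
III all treated, IV–VI the control analogues, VII everyone.  A
45-parameter catalogue yields 45² = 2025 tasks per (time, population,
prototype) slice and 2025 · 6 · 7 · 6 = 510 300 regressions for the
full study grid.  Every fitted optimum carries a parseable search key
(`P3~P17@t300|III|sigmoid`) for traceability.

Postprocessing filters candidates (GoF ≥ 0.7 and n ≥ 12 by default),
forms population-difference matrices, ranks gof time courses by their
max − min change, labels pairs lockstep/early/late, seriates matrices
for cluster hints, and can attach an exploratory permutation p-value to
individual pairs.

## Worked example

`examples/generate_and_screen.py` plants a noisy sigmoid coupling
between P1 and P2 in a 30-subject synthetic cohort and screens all
pairs with all six prototypes:

```
CrudeDatabase(4 parameters, 30 subjects, 120 measurements, time grid [0])
screening 96 regression tasks ...

best goodness of fit (1 = perfect, 0 = no better than the mean):
       P1     P2     P3     P4
P1  1.000  1.000  0.144  0.170
P2  0.973  1.000  0.165  0.091
P3  0.133  0.160  1.000  0.184
P4  0.051  0.083  0.067  1.000

winning prototype per cell:
         P1       P2       P3           P4
P1   linear  sigmoid  sigmoid      sigmoid
P2    cubic   linear  sigmoid  exponential
P3  sigmoid  sigmoid   linear        cubic
P4  sigmoid  sigmoid  sigmoid       linear
```

The planted (P1, P2) cell reaches GoF 1.000 with the sigmoid family;
the diagonal is trivially perfect (each parameter against itself, fitted
but flagged as trivial downstream); unrelated cells stay far below the
0.7 candidate threshold.  The other examples demonstrate the
population-difference ranking, time-trend classification and the
permutation test.

There is also a thin CLI over the same library:

```bash
pairscreen generate --out cohort --plant P1:P2:sigmoid:0.01
pairscreen screen --input cohort/cohort.tsv --out screen_out
pairscreen filter screen_out/best_results.tsv --min-gof 0.7 --min-n 12
pairscreen diff --dir screen_out --pop-a I --pop-b II --time 0
```

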