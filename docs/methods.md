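# Methods

## The two cross entropies

Both statistics compare the delay-embedded templates of one series against
those of the other under the Chebyshev metric, with `N − m` templates at both
orders `m` and `m + 1` (indices 1..N−m), so the two orders average over
equally many template pairs. Matching is direction-free: the grand mean over
all (N−m)² pairs is symmetric in the two series.

**C-SampleEn** uses the strict Heaviside match `d < r`, no baseline removal,
and reports `−ln(B^{m+1}/B^m)`. The defining ratio is sometimes printed the
other way up in the literature; that orientation is negative for Heaviside
matching (B^{m+1} ≤ B^m always, since an order-(m+1) match implies the
order-m match), so this package uses the orientation that yields the
conventional nonnegative values. When either match fraction is zero the
statistic is undefined; this is returned as a flagged `nan`
(`CrossEntropyResult.defined`), never an exception, because sweep code needs
to tabulate definedness rates.

**C-FuzzyEn** subtracts each template's window mean at both orders and
weights pairs by `exp(−d^n / r)`. The ratio is evaluated in log space
(`logsumexp`), because for tolerances as small as 1e−4 on unit-scale data the
memberships underflow to zero in double precision even though the statistic
is mathematically finite; the log-space form keeps the measure total down to
`N = m + 2` and `r = 1e−4`.

A structural consequence of baseline removal worth knowing: every order-1
template centres to the zero vector, so `phi^1 ≡ 1` and
`C-FuzzyEn(m=1) = −ln(phi^2)`. The m = 1 value is therefore systematically
about half the m = 2 value; the downward drift of the statistic with
embedding dimension holds from m = 2 on.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `m` | template length | 2 (simulations), 1 (gait) | short series need small m |
| `r` | tolerance, absolute, series units | — | not scaled by SD; an opt-in z-score flag exists |
| `n` | fuzzy boundary exponent | 2 | the conventional value |

`r` is deliberately absolute: the gait screening grid reaches 1e−4 s on
second-valued stride times, which only makes sense unscaled.

## Surrogate signals

**MIX(p)**: the unit-variance sine `√2·sin(2πj/12)`, j = 1..N, with
`round(p·N)` distinct positions (sampled uniformly without replacement)
replaced by i.i.d. Uniform(−√3, √3) draws — both components unit variance, so
disorder rises with p at constant scale. The deterministic component is
identical in every MIX series; two independently generated MIX series
therefore share exact values wherever neither was substituted, which
guarantees zero-distance cross matches and keeps C-SampleEn defined on these
pairs at every (r, N). Constructions that randomise the sine phase per series
remove those exact matches but roughly triple the run-to-run spread; this
package keeps the fixed-phase construction of the original proposal.

**i.i.d. uniform** experiment signals are zero-mean unit-variance
Uniform(−√3, √3) — the same scale convention as the MIX components — so the
absolute tolerance grid spans 0.01 to ~1 series-SD and the C-SampleEn
tolerance floor is actually exercised. (On Uniform(0,1) data an absolute
r = 0.3 is ≈ 1.04 series-SD and C-SampleEn never goes undefined at any
length, which would make the length-sweep comparison vacuous.)

**Synthetic gait pairs** are fixture machinery, not a biomechanical model:
`limb = base + coupling·shared + (1 − coupling)·own`, where `shared` and each
limb's `own` fluctuation are stationary AR(1) processes (lag-1 coefficient
0.9) scaled to `noise_sd`, with optional turnaround-style outliers (a point
multiplied by Uniform(2, 4)). Defaults for cohorts: base stride 1.1 s;
control-like coupling 0.95 with noise SD 0.025 s; PD-like coupling 0.30 with
noise SD 0.045 s (weakly coupled, more variable); series lengths drawn
uniformly from 170–260 strides; outlier rate 0.02. These emulate the
magnitudes of real stride-interval records (stride-time CV of a few percent,
higher variability and weaker bilateral synchrony in parkinsonian gait) but
none of their long-range correlation structure, nonstationarity, or
age/severity heterogeneity — so passing tests demonstrate that the pipeline
recovers a built-in group difference, not that it would achieve any
particular performance on clinical data.

## Monte-Carlo experiments

Each parameter point uses 200 fresh pairs. Seeding is hierarchical: every
(experiment, parameter point, run) triple derives its own child generator
from the master seed, so results are reproducible bit-for-bit and independent
of evaluation order. Undefined C-SampleEn runs are excluded from means/SDs
and tracked as a defined fraction; aggregate statistics (mean of per-N or
per-r SDs, SD of per-N means) drop parameter points with defined fraction
≤ 0.5 by default (configurable), since a mean over a handful of surviving
runs is not comparable to a fully defined point.

The tolerance grid is [0.01 : 0.01 : 0.1] ∪ [0.11 : 0.1 : 1] taken literally
(19 values, topping out at 0.91); the length grid is 50..500 in steps of 50
with r = 0.3 and m ∈ {2, 3}.

Observed behaviour under these conventions, all recomputed by
`scripts/acceptance.py` and the acceptance tests: C-FuzzyEn is defined
everywhere with per-N SDs about 6× smaller than C-SampleEn's and per-N means
nearly constant in N; C-SampleEn loses definedness at short lengths (m = 3
at N = 50) and at small tolerances in the r sweep; and C-FuzzyEn orders the
(MIX(0.2), MIX(0.3)) pair below the (MIX(0.3), MIX(0.4)) pair at every
tolerance for both N = 100 and N = 50, the relative-consistency property.
Published figures for some of these aggregates are larger than what this
construction yields (uniformly ~25–60% across unrelated experiments); since
the surrogate-generation details that would explain the gap are not
recorded in the source material, the generators here follow the cited
constructions and the aggregates are reported as computed.

## Gait pipeline

* **Outlier rule**: drop points outside median ± 3·SD (the robust centre with
  a full-series SD); multiplier configurable. Removal is *paired*: the union
  of left and right outlier indices is dropped from both series, so stride i
  on one limb stays aligned with stride i on the other. Independent per-limb
  removal would desynchronise the limbs and corrupt the cross statistics.
* **Window**: the first `N_use` (default 150) retained strides per limb;
  subjects with fewer fail loudly rather than silently shortening.
* **Features**: C-FuzzyEn(m=1, n=2, r), C-SampleEn(m=1, r) on the
  (left, right) pair, and ASI from the per-limb mean stride interval over the
  same window (the most common clinical choice for the scalar feature T;
  configurable).
* **Tolerance screen**: for each r in [0.0001 : 0.0001 : 0.001] ∪
  [0.002 : 0.001 : 0.01] (a coarser [0.02 : 0.01 : 0.1] tail is opt-in),
  two-sided Mann–Whitney U on per-subject C-FuzzyEn between groups; the
  selected r minimises p. The test is exact (scipy) when both groups have ≤ 8
  tie-free observations, otherwise the tie-corrected normal approximation.

## Classification

Leave-one-out evaluation of an RBF-SVM on a single feature (or feature
vector). Inside each training fold only: features are standardised and the
kernel width set by the median heuristic (γ = 1/(2·median pairwise
distance²)); C = 1. Nothing from the held-out subject reaches its own
prediction. Decision values at exactly 0 resolve to the negative (control)
class; a zero-variance training fold yields a negative prediction and clears
the report's `informative` flag. ROC area is the rank-based estimator
(probability a positive outscores a negative, ties half) computed from the
held-out decision values — a binormal-fit AUC is deliberately out of scope.
Min-max normalisation is provided for display only and is never part of the
classifier path.

## Numerical notes and limitations

* Heaviside comparison is strict (`d < r`); `d == r` is not a match.
* Template counts are equal at both orders; the last order-m window is
  dropped.
* The synthetic cohort's group separation is an input, not a finding; LOO
  accuracy of 100% on it (README example) reflects the chosen coupling gap,
  not expected clinical performance.
* Entropy values at m = 1 lean entirely on the order-2 statistic (see above);
  screens comparing groups at m = 1 are unaffected because the depression is
  common to both groups.
* The Monte-Carlo aggregates carry sampling error of a few percent at 200
  runs; the SD-of-10-means statistics (length sweep) are the noisiest, with
  seed-to-seed spread comparable to their own magnitude.
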