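# xfuzzen

Cross-fuzzy entropy (C-FuzzyEn) and cross-sample entropy (C-SampleEn) for
bilateral gait symmetry analysis, with the Monte-Carlo validation experiments
that motivate preferring the fuzzy variant on short physiological series, and
a complete stride-interval pipeline: turnaround-outlier removal, per-subject
symmetry features (C-FuzzyEn, C-SampleEn, the absolute symmetry index),
Mann–Whitney tolerance screening, and leave-one-out RBF-SVM classification of
parkinsonian vs. control gait.

## The statistics

Given two equal-length series *u*, *v*, form the delay-embedded templates
*x<sub>m</sub>(i) = (u(i), …, u(i+m−1))* and likewise *y<sub>m</sub>(j)*, and
measure template distance with the Chebyshev metric
*d = max<sub>k</sub> |u(i+k) − v(j+k)|*.

**C-SampleEn(m, r, N)** counts hard matches, θ(d) = 1 iff d < r, averages them
over all (N−m)² template pairs to get B<sup>m</sup>, repeats at order m+1, and
reports −ln(B<sup>m+1</sup>/B<sup>m</sup>). With no self-matches to guarantee
a nonzero count, it is **undefined** whenever no cross-template pair matches —
which happens routinely for small r or short series.

**C-FuzzyEn(m, n, r, N)** replaces the hard threshold with the fuzzy
membership exp(−d<sup>n</sup>/r) (n = 2 by convention) and removes each
template's own baseline (window mean) before comparison, emphasising shape
over level. Every membership is positive, so the statistic is defined for
*every* valid input — the property that matters for gait records a few
hundred strides long.

Low values mean the two series share many local patterns (a symmetric,
synchronised gait); high values mean pattern dissimilarity (asymmetric gait).
The scalar baseline is ASI = 100·(T<sub>R</sub> − T<sub>L</sub>)/(0.5·(T<sub>R</sub>
+ T<sub>L</sub>)) with T the mean stride interval per limb.

## Worked example

Screen the entropy tolerance on a synthetic two-group cohort (15 "PD-like"
subjects with weak cross-limb coupling, 16 "control-like" subjects with
strong coupling), extract features, and classify:

```python
from xfuzzen import EntropyParams, feature_table, loo_svm, select_r
from xfuzzen.simulate import synthetic_cohort

records = synthetic_cohort(seed=0)
best_r, screen = select_r(records)          # Mann-Whitney screen over the r grid
print(best_r, screen.p_value.min())         # 0.0001 2.316463851638489e-06

table = feature_table(records, params=EntropyParams(m=1, r=best_r, n=2))
print(table.groupby("group").cfuzzyen.mean())
# CO    0.382343
# PD    0.617117

report = loo_svm(table.cfuzzyen.to_numpy(), table.group.to_numpy(), positive="PD")
print(report.accuracy, report.roc_area)     # 100.0 1.0
asi = loo_svm(table.asi.to_numpy(), table.group.to_numpy(), positive="PD")
print(asi.accuracy)                         # 77.42
```

The PD-like group carries visibly higher cross-fuzzy entropy (0.62 vs 0.38
at the selected tolerance), the screen flags the separation at p ≈ 2·10⁻⁶,
and the entropy feature classifies the cohort perfectly under leave-one-out
while the ASI baseline reaches 77.4% — mean stride times barely differ
between limbs in this construction, so a level-based index discriminates far
less than a pattern-based one.

A thin CLI mirrors the library (`xfuzzen entropy|simulate|experiment|gait|classify --help`).

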