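# Methods

## The model

`mcopa` treats an expression study as a features × samples grid of log2-scale
normalised intensities whose leading *n* columns are normal/control samples.
The quantity of interest is not a per-feature group difference but the set of
(feature, sample) pairs in which a feature is expressed far outside its own
typical range — outliers in the sense of the sample's position within the
feature's distribution, not the feature's position within the sample.

**Robust standardisation.**  Each feature is centred on its median across all
samples and divided by a robust scale so that a handful of extreme samples
remain visible (mean/SD standardisation would let them inflate the scale and
mask themselves).  The default scale is the mean absolute deviation from the
median; the median absolute deviation (un-normalised — no 1.4826 consistency
factor) is selectable via `scale_mode="mad"`.  The mean-AD is the package's
default because it is the scale the method family historically standardised
to 1.0; the median-AD variant is offered because it is the more common robust
scale in the wider outlier literature and is more resistant when a large
fraction of samples is shifted.  Features with zero scale are flagged
degenerate and excluded from calling.

**Feature-specific fences.**  Outlier thresholds are per feature, computed
from the *tumour* samples only: Q75 + 1.5·IQR and Q25 − 1.5·IQR of the
transformed tumour values (classical Tukey fences).  The fences are applied
to all samples, normals included — outliers arising in normal tissue are
informative for the filter below.  Fence comparisons are strict; a value
exactly on the fence is not an outlier.  Features with zero tumour IQR are
treated as degenerate (a zero-width fence would call every deviation an
outlier).  Because the fence is an upper-quartile statistic, it breaks down
when more than ~25% of the tumour group carries the shift; recurrent lesions
beyond that fraction are differential expression, not outliers, and are
invisible to this method by construction.

**Three retention criteria.**  Per direction (up/down), a feature is retained
iff (1) it has at least one outlier call in a tumour sample; (2) it has no
outlier call *of the same direction* in any normal sample — an
opposite-direction normal outlier does not disqualify it; and (3) the
nominated upper (down: lower) percentiles of the tumour and normal groups are
separated by more than the fold-change threshold (default 2).

**Criterion-3 scale (`fc_scale`).**  The nominated percentiles are computed
from the transformed values, and the default comparison
(`fc_scale="copa"`) is the absolute difference of those transformed
percentiles.  Rationale: the transformed scale is where the whole workflow
operates; a difference there is the feature's log2 fold change measured in
units of its own robust spread, giving a feature-specific threshold in the
same spirit as the feature-specific fences, and it avoids ratios of signed
standardised scores, which are ill-defined near zero.  Two alternatives are
provided: `"log2input"` compares the percentiles of the raw (log2) input
values, so the threshold is a plain log2 fold change; `"ratio"` takes
log2 |p_t / p_n| of raw linear-scale percentiles for inputs that were never
log-transformed (an undefined ratio fails the criterion).  On strongly
heteroscedastic data the three modes select different features; the mode is
logged with every run.

**Percentile estimation.**  All quantiles in the pipeline — fences, nominated
percentiles, ranking scores — use one interpolation rule, by default the
median-unbiased rule (Hyndman–Fan type 8), the standard recommendation when
the underlying distribution is unknown.  All nine classical types are
selectable by number or name; estimates from 10–30 values differ materially
between rules, which is why the rule is an explicit parameter.

**Profiles and summaries.**  Retained features form a dense code table over
all samples (1 over-expressed outlier, −1 under-expressed, 0 neither; a cell
can never be both, because the upper fence is never below the lower fence).
From the profile: subtype-exclusive outliers (features whose calls all fall
inside a nominated sample set; non-exclusive membership is selectable, and
direction defaults to "both"), per-sample outlier lists (the profile's
inversion), and sharing histograms (how many selected samples carry each
outlier, plus the count of features whose outliers all fall outside the
selection).

## Preprocessing

Features, then samples, with more than 40% missing entries are dropped (one
pass each, features first; both counts are logged).  Remaining missing cells
are imputed by the mean of the k = 10 nearest features' values in that
column, with nearness the Euclidean distance over the samples observed in
both features, normalised by the number of shared samples so that candidates
with different missingness patterns are comparable; distance ties are broken
by feature order for determinism.  This imputation is written in-package
because the required tie-breaking and shared-sample distance rule differ from
the row-scaling conventions of library imputers.

## Evaluation harness

Four selectors are compared by how well their features cluster tumour samples
into annotated subtypes:

- **outlier selection** — the union of up- and down-retained features;
- **percentile ranking** — features ordered by the nominated upper percentile
  of their transformed tumour values (an over-expression ranking), truncated
  to the outlier selection's size;
- **differential expression stand-in** — per-feature Welch t-test (normal vs
  tumour) with Benjamini–Hochberg adjustment at α = 0.01.  A moderated-t
  (shrinkage) analysis is deliberately not reimplemented: the comparator's
  role here is relative benchmarking, and the stand-in is labelled as such;
- **variance** — the top 1000 features by overall sample variance.

Clustering runs on the selected-feature submatrix of tumour samples with
Euclidean distance and no further scaling.  k-means is the best of 20
independently seeded runs by within-cluster sum of squares (batch Lloyd
iterations; the classical online-update variant is not available in
scikit-learn, and the best-of-repeats protocol makes the iteration style
immaterial in practice).  PAM (partitioning around medoids, BUILD + SWAP) is
implemented in-package — no installed Python library provides it — and is
cross-checked against R's `cluster::pam` on frozen fixtures in the test
suite.  The number of clusters is supplied (by default the number of
annotated subtypes, after removing subtypes with three or fewer samples).

Agreement is the adjusted Rand index computed from the pair-count contingency
table; it is 1 for identical partitions and has exact expectation 0 under
random relabelling with fixed cluster sizes.  When the chance-corrected
denominator is zero (e.g. both partitions all-singleton) the index is defined
as 1 if the partitions are identical, else 0.  Any externally produced
partition can be scored by wrapping its labels in a `Partition`.  Selector
score distributions are compared with the Kruskal–Wallis rank test
(tie-corrected H, chi-squared p-value; all-identical scores give H = 0,
p = 1).

## Synthetic data

The generator emulates the data regime the method targets: a log2-scale
matrix with pure-background normal samples, tumour subtypes, and features
extreme in only a few tumours.  Defaults — the study conditions used
throughout the tests — are 2000 features, 10 normal + 20 tumour samples in
two subtypes of 10, per-feature baselines N(8, 1.5²) log2 units, measurement
noise SD 0.5, and three planted classes:

- **outlier features** (200; 10%): ±4 log2-unit shifts in 10% of the tumour
  group, direction mix 0.5.  Half are *subtype-specific*: the affected
  samples are drawn from a single subtype, recurrently in 30% of its members.
  The recurrence fraction matters: a feature outlier in one sample of ten
  cannot define a subtype by construction, while a shift in more than ~25% of
  the tumour group breaks the Tukey fence itself; 0.3 of a 10-sample subtype
  (15% of the tumour group) is within the method's detection envelope and
  mimics recurrent lesions that characterise a subtype in real data.
- **differential-expression features** (100): +2 log2 units in every tumour.
- **noise features** (100): SD 2.0, no group structure — the classical trap
  for variance-based selection.

Normal samples carry no planted effects, matching the filter's assumption
that retained features are outlier-free in normals.  Each feature draws from
its own counter-derived substream of the master seed, so enlarging the matrix
leaves existing features unchanged.  Infeasible settings (an affected-sample
count that rounds to zero, planted counts exceeding the feature count) raise
at construction.

Recovery is scored per direction at feature level and (feature, sample)
level; with no calls at all, precision is reported as 1 by convention (no
false claims) and recall as 0.  The recovery benchmark in the test suite
plants only outlier features (no DE, no noise): a DE feature that also
contains a chance extreme tumour sample is genuinely ambiguous truth for
outlier scoring, and the benchmark should measure the estimator, not the
ambiguity of its target.  Under those conditions (20 seeds) mean feature
precision and recall exceed 0.9 and the no-effect false-positive feature rate
stays below 1%.

What passing these tests does *not* show: the generator's noise is Gaussian
and homoscedastic, with no batch effects, probe cross-hybridisation,
correlated features or heavy tails, so performance on real arrays — where the
fences face heavier-tailed within-feature distributions — will be somewhat
worse than the synthetic figures.

## Problem sizes and numerical choices

Simulated studies use 2000 features × 30 samples with 20-replicate designs,
sizes at which every experiment in the suite completes in seconds while
keeping Monte-Carlo error on recovery rates near 1%.  Determinism: all
randomness flows from explicit integer seeds (generator substreams, k-means
repeat seeds); PAM and the filters are deterministic; output files contain no
timestamps, so re-runs are byte-identical.  Quantile agreement with
independent implementations is asserted to 1e-12; fence comparisons are
strict inequalities, so boundary values are non-outliers by convention.

## Known limitations

- Outliers recurrent in more than ~25% of tumours defeat the quartile fence
  (see above); such features surface via the DE comparator instead.
- With very few normal samples the nominated normal-group percentile is
  noisy, which is the main source of false-positive retained features.
- The DE comparator is a Welch-t stand-in, not a moderated-t analysis; its
  feature lists on small studies will differ from shrinkage-based tools.
- Automatic cluster-number selection is out of scope; the harness expects the
  cluster count (or derives it from the annotation).
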