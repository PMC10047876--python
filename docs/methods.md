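# Methods

## The classification rule engine

The Schroth curve-type algorithm is a small decision tree over four
boolean postural judgements supplied by a human rater:
`pelvis_balanced`, `pelvis_lumbar_coupled`, `prominent_hip`,
`thoracic_dominant`. The engine is total and deterministic over all 16
combinations:

* pelvis displaced + coupled → `3cp`; pelvis displaced + uncoupled →
  `4cp` (hip prominence and thoracic dominance are recorded in the trace
  but cannot change the label on this branch);
* pelvis balanced → the thoracic-vs-lumbar prominence comparison decides
  `3c` vs `4c`. The clinical description also mentions checking coupling
  and hip prominence on this branch without stating an alternative
  outcome when they fail; we treat them as confirmatory observations
  only, because the prominence comparison is the stated deciding step
  and the function must be total. A tie between prominences must be
  encoded as `thoracic_dominant=False` and therefore yields `4c`, the
  "otherwise" label.

Curve laterality (left/right convexity) is deliberately not part of the
label: the engine classifies the pattern, not the direction.

## Agreement coefficients

All statistics operate on a subjects × raters table of categorical
ratings over a fixed category list of size `q = 4`. `q` is taken from
the declared list even if a rater never used a category, so chance
agreement always reflects the design, not the sample.

Observed agreement averages, over subjects with at least two ratings,
the expected weight of a randomly chosen pair of ratings of that
subject. Chance agreement uses the average category propensities
`π_k` and equals `(T_w / (q(q−1))) Σ_k π_k(1−π_k)`. The coefficient is
`(p_a − p_e)/(1 − p_e)`. Identity weights give the unweighted AC1
exactly — the weighted code path is the only code path — and the
pairwise-enumeration equivalence of `p_a` is enforced by tests against a
deliberately naive oracle.

Missing ratings: a subject rated fewer than twice contributes nothing to
`p_a` but its available ratings still enter `π_k`. This convention is
forced by the arithmetic of published per-rater percent agreements with
denominators smaller than the full sample.

Intra-rater reliability treats one rater's two occasions as a two-rater
table; inter-rater reliability is the multi-rater coefficient at one
occasion. Because published reports often print a single inter-rater
value without naming the occasion, the pipeline reports both occasions
and their Fisher-pooled mean rather than silently choosing one.

### Variance and intervals

Standard errors come from a subject-level delete-one jackknife, the
standard resampling choice when subjects are the independent units and
no closed-form variance is stated for the exact estimator variant in
use. 95% intervals are `estimate ± 1.96·se`, truncated above at 1 (a
coefficient cannot exceed 1) and not truncated below. The jackknife is
positive whenever subjects disagree and shrinks like `1/√n`; both
properties are tested.

## Pooling, benchmarking, precision

Group summaries use Fisher's z: `tanh(mean(atanh(c_j)))`, with a CI from
the standard error of the mean in z space, back-transformed. Pooling a
single value returns it unchanged; values of exactly ±1 are rejected
(infinite transform). Inside the report pipeline, boundary estimates
from perfect simulated studies are nudged by 1e−12 before pooling so a
group of perfect raters reports 1.00 instead of an error.

Benchmarking subtracts a configurable critical value (default 0.08,
appropriate for 44 subjects, 10 raters, 4 categories) from the estimate
and bands the remainder on a Landis–Koch-style scale (<0 poor, 0–0.20
slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial,
0.81–1.00 almost perfect). Deriving the critical value itself is out of
scope; it is an input. Clinical adequacy is a separate flag on the raw
estimate, threshold 0.61, boundary inclusive.

Precision criteria follow agreement-study sample-size practice: the
coefficient of variation of percent agreement (`se/p_a`) must be ≤ 0.15
and the relative error ≤ 0.20. "Relative error" is interpreted as the
95% CI half-width over `p_a`; because the phrase is ambiguous between
half- and full-width, both are computed and the half-width is the
flagged metric.

## The synthetic-study generator

The generator emulates the reference study design: 44 subjects with
curve-type prevalence 9/12/6/17 over (`3c`, `3cp`, `4c`, `4cp`), ten
raters, two rating occasions at least a week apart, occasional missing
ratings. Each rater has

* `accuracy` a ∈ (0,1]: probability of the true category on a fresh
  look (default tiers 0.90 / 0.75 / 0.60 for experienced / well-trained
  / other raters, mirroring the 50–100% range of self-reported algorithm
  understanding);
* `consistency` c ∈ [0,1]: probability the second-occasion label copies
  the first (defaults 0.20 / 0.15 / 0.10 — deliberately low because
  raters were blinded to their first-round labels and saw the subjects
  re-ordered, so occasion 2 is mostly a fresh judgement with modest
  carry-over);
* `missing_rate` (default 0.01, reproducing the occasional absent
  rating).

Error topology: a miss lands on another category with probability
proportional to its clinical-similarity weight to the truth, with zero
weights floored at ε = 0.05 so every confusion remains possible. This
encodes that `3c↔3cp` and `4c↔4cp` are confusable while
opposite-treatment pairs are rarely interchanged. No empirical
per-pair misclassification counts exist for this assumption; it is a
modelling choice.

The model yields a closed form used as the recovery oracle:
`E[p_a] = Σ_t π_t [c + (1−c) Σ_k C[t,k]²]`, conditioning on both
ratings being observed.

Subgroups are nested as in the reference design: the experienced pair
also belongs to the well-trained group (they are the raters with full
command of the algorithm). This nesting is what produces the
characteristic ordering experienced > well-trained > all; with disjoint
groups the full-panel mean can overtake the well-trained mean.

What the generator does **not** emulate: video quality, branch-level
(feature) rater errors, learning between occasions, and any dependence
of accuracy on the true category beyond the similarity spreading.
Passing recovery tests therefore validates the statistics pipeline and
the generator's own model — not the behaviour of human raters on real
patients.

## Problem sizes in validation

Stochastic checks use 200 replicate studies per condition with
3-Monte-Carlo-standard-error tolerances (parameter recovery), 200
replicates per grid point for monotonicity in a over {0.5, 0.7, 0.9}
and c over {0.5, 0.8, 1.0} with four-rater panels, 20 replicates for
the subgroup-ordering check, and 1,000 random small matrices (≤ 5
subjects, ≤ 3 raters, 25% missingness) for formula-vs-enumeration
equivalence at 1e−12. These sizes make every check stable under seed
changes while keeping the suite fast.

## Known limitations

* The jackknife CI is a normal approximation; for coefficients near 1
  with few subjects, its coverage is approximate and the upper truncation
  makes intervals asymmetric.
* Fisher pooling weights every rater equally; it does not
  inverse-variance weight, matching the convention of reporting a plain
  transformed mean.
* The generator's confusion structure is an assumption (see above);
  conclusions about real raters require real ratings.
* Pooled-CI construction for group rows (se of the mean in z space) is
  one reasonable choice among several; only the point estimates are
  benchmarked against published values.
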