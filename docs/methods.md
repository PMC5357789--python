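# Methods

## The problem

Circulating exosomal miRNAs are attractive diagnostic analytes — they are
RNase-protected and condition-specific — but quantifying them by qRT-PCR
has no credible normalization standard: exosomes carry no background
transcriptome from which housekeeping references could be chosen, and the
RNA yield of an exosome preparation varies strongly between samples,
instruments and sites. `exopair` implements a screening workflow that
removes the need for a reference gene altogether, applied to the
discovery of a serum exosomal miRNA panel for Kawasaki disease (KD), an
acute paediatric vasculitis that presents like several common febrile
infections (adenovirus, EBV, juvenile idiopathic arthritis, scarlet
fever) but requires rapid, specific treatment (IVIG).

## Stage 1 — pooled-array candidate screen

Inputs are vendor-normalized log2 intensities of ~1900 miRNA probes for
three pooled conditions (Normal, KD, KD after IVIG), compared as
Normal-vs-KD and KD-vs-+IVIG. Candidates are probes with an *on/off
switch* in **both** comparisons: log2 intensity > 3.5 on one side, below
the −3 detection floor on the other, and a > 200-fold linear change. A
second direction — *opposite tendency* — keeps probes abundant only in
KD (log2 > 4.5) and undetected in both Normal and +IVIG.

All thresholds are strict inequalities and are exposed in
`ArrayScreenCriteria`. The fold change is computed by default on
intensities **floored at the detection limit** (signals below the floor
are noise, so a raw fold would manufacture spurious magnitude from two
noise values). One consequence worth knowing: because the floor equals
`off_threshold`, lowering `off_threshold` both tightens the off
predicate *and* inflates floored folds, so candidate sets are not
monotone in that one parameter; with `floor_fold_at_off=False` they are.
Near the floor the on/off predicate, not the fold rule, binds (a probe
at (4.0, −3.5)/(3.8, −3.2) passes on/off but its floored fold is
2^7 = 128 < 200 and it is not selected).

The clustergram uses agglomerative clustering of probes on their two
intensities, Euclidean metric, Ward linkage (`scipy.cluster.hierarchy`);
`cluster_profiles` reports the linkage and the top-three branch sizes.

## Stage 2 — reference-free pairwise ΔCT screen

For each sample *s* and ordered candidate pair (*i*, *j*),

&nbsp;&nbsp;&nbsp;&nbsp;ΔCT<sub>ij</sub>(s) = CT<sub>s</sub>(i) − CT<sub>s</sub>(j).

CT is a log-scale quantity (one cycle ≈ 2-fold), so any per-sample
multiplicative bias — extraction yield, input volume, storage history —
appears as an additive per-sample constant and cancels exactly in every
ΔCT. Trying *every* candidate as the reference for every other turns the
normalization problem into an all-pairs screen.

Processing steps, in order:

* **Replicate averaging** — arithmetic mean of the replicate CTs per
  (sample, miRNA) cell (triplicates in the study design).
* **Quantifiability ceiling** — any miRNA whose averaged CT exceeds 35
  cycles in *any* cohort sample is removed entirely (strict: CT = 35.0
  is kept). Masked cells do not trigger removal; missingness is handled
  later by per-pair complete-case analysis.
* **P-value matrices** — for each declared group comparison, a matrix
  over ordered pairs with P[i, j] the two-sided pooled-variance Student
  t-test p-value comparing ΔCT<sub>ij</sub> between the two groups
  (Welch variant available behind `equal_var=False`, not default). The
  pooled-t statistic is computed vectorised over all pairs with
  NaN-aware sufficient statistics so each cell automatically uses its
  pairwise complete cases; the distribution function is `scipy.stats.t`.
  Matrices are symmetric (a two-sided test is invariant to negating the
  data) with an undefined diagonal. Cells where both groups have zero
  within-group variance are flagged degenerate and set to p = 1 (equal
  means) or p = 0 (unequal).
* **Selection** — a *forward* biomarker pair is significant
  (p < α = 0.01, strict) for KD-vs-Normal and KD-vs-+IVIG and
  non-significant (p > α) for Normal-vs-ADV; an *opposite* pair
  satisfies the exact inversion (the treatment-insensitive,
  infection-sensitive direction). The inversion is one reading of
  "completely opposite trend"; it is a package choice, not the only
  possible formalization. Unordered duplicates are reported once,
  oriented so the target is the member with the larger |mean CT shift|
  in KD-vs-Normal (lexicographic tie-break). No multiple-testing
  correction is applied in the default screen; `stricter_screen` counts
  pairs below a harsher level (10⁻⁴) instead, which is how the workflow
  probes robustness of its shortlist.

### Why pooled-t, and how it was validated

"Student's t-test" here means the classical pooled-variance test. Two
independent routes check the implementation: `scipy.stats.ttest_ind` on
individual pairs (library route), and an exhaustive permutation
enumeration (`permutation_pvalue`, model-free route) that enumerates all
C(n₁+n₂, n₁) relabelings of the pooled observations and counts those
with |t| at least the observed.

A note on what "agreement with the permutation test" can mean at small
n: with 4-vs-4 groups the enumeration has only 70 relabelings, the
permutation p lives on a lattice with floor 2/70 ≈ 0.029, and the
conditional (permutation) and unconditional (t) p-values differ by
O(1/n) in the mid-range. Empirically the mean |p_t − p_perm| over null
instances is ≈ 0.03–0.04 and the maximum ≈ 0.1–0.2; these are properties
of the two tests, not implementation error (the enumeration matches
`scipy.stats.permutation_test` exactly). The package therefore states
its calibration bounds as: mean deviation ≤ 0.06, max ≤ 0.25, and
whenever p_t falls below the lattice floor the enumeration places the
observed labeling within two lattice steps of that floor.

## Stage 3 — two-pair nearest-centroid diagnosis

The validated panel gives each sample two offset-invariant features,
f1 = CT(miR-1246) − CT(miR-4436b-5p) and
f2 = CT(miR-197-3p) − CT(miR-671-5p). Three classes are used: Normal,
KD, and non-KD febrile (ADV, EBV, JIA and SF pooled). The decision rule
is nearest centroid by Euclidean distance — the simplest rule consistent
with the three-cluster geometry of the feature space — with
deterministic tie-break by declared class order and a pluggable model
object for anything fancier.

Different sites use different instruments and reagents, which shifts the
features additively per centre. `fit_centroids` therefore accepts
designated *standard samples*: each centre with ≥ 3 labelled standards
gets an additive offset equal to the component-wise median residual of
its standards from their true-class centroids (median for robustness at
the handfuls of standards realistically available); centres without
enough standards get zero offset. When calibration ids are drawn from
the training set they are excluded from the centroid means so a shifted
centre cannot drag the centroids.

## The synthetic cohorts

The generator is first-class code: it produces data with exactly the
statistical structure the analysis assumes, plus a truth record, so
every stage is testable without downloads.

CT model (all terms in cycles):

    CT(s, m, r) = baseline(m) + effect(group(s), m) + offset(s)
                  + centre(c(s)) + centre_mirna(c(s), m) + ε,
    offset(s) ~ N(0, sample_offset_sd),  ε ~ N(0, replicate_sd)

Additive Gaussian noise on the CT scale is the conventional qPCR error
model (CT is already logarithmic). `offset(s)` is the
extraction-efficiency nuisance that self-referencing must cancel
*exactly*; the scalar per-centre term cancels likewise, while the
per-(centre, miRNA) term survives ΔCT and is what the classifier's
calibration exists to remove. One shared RNG stream per generation call;
identical config + seed reproduces identical output byte for byte.

Microarray model: background probes iid N(0, 1.5) per condition in log2
units; planted on/off probes draw U(5, 7) on their "on" side and
U(−6, −3.3) below the floor, so they clear both the on/off and the
floored > 200-fold rule by construction; opposite-tendency probes are
high only in KD. With the default background, the chance of a spurious
on/off candidate across both comparisons is ~10⁻³ per 1887-probe array.

### Scenario defaults (the study conditions)

* **Screening cohort**: 20 Normal / 20 KD / 20 +IVIG / 5 ADV, 11-miRNA
  candidate panel, triplicates, replicate_sd 0.3 cycles,
  sample_offset_sd 1.0 cycles, fixed baselines 21–25 cycles (kept below
  the 35-cycle ceiling even under the largest planted shift). One
  forward pair is planted (miR-1246 over reference miR-4436b-5p, −3
  cycles in KD only) and one opposite pair (miR-197-3p / miR-671-5p,
  equal −2-cycle KD shifts that cancel within the pair, ADV shifts
  differing by 2 cycles). Every other panel member carries mutually
  distinct KD *and* ADV effects (pairwise gaps ≥ 1 cycle for KD, ≥ 2 for
  ADV — many cycles beyond detectability at these group sizes), which
  makes the planted pairs the *unique* solutions: any non-planted pair
  has either a detectable KD-effect gap (breaking the non-significance
  half of the opposite criteria) or a detectable ADV-effect gap
  (breaking the Normal-vs-ADV non-significance half of the forward
  criteria). Recovery is then limited only by the three exact-null
  p > 0.01 requirements, each satisfied with probability 0.99 per
  cohort, giving ≈ 0.97 per-seed probability of exact recovery —
  observed 98% over 300 seeds.
* **Null cohort**: 20 vs 20, 11 miRNAs, no effects — for type-I
  calibration. ΔCT features of different pairs are correlated (they
  share miRNAs), so the rejection *rate* is assessed on its mean across
  seeds.
* **Validation cohort**: 54 Normal / 54 KD / 36 non-KD febrile
  (10 ADV + 13 EBV + 12 JIA + 1 SF) over the 4 panel miRNAs, two
  centres; class centroids at (0, 0), (−5, 0) and (−5, −5) in (f1, f2),
  so f1 alone cannot split KD from febrile and f2 alone cannot split KD
  from Normal — the geometry that forces a combined two-pair criterion.
  Within-class feature SD ≈ 0.5 cycles (replicate_sd 0.6, triplicates).
  Centre2 carries a +2-cycle per-miRNA instrument shift on both target
  miRNAs (shifting both features by +2) plus a +1-cycle global offset
  that ΔCT cancels on its own.

What the generator does **not** emulate: amplification-efficiency
differences between assays, CT-dependent (heteroscedastic) noise,
non-Gaussian dropout near the detection limit, hemolysis or other
pre-analytic covariates beyond the global offset, and any correlation
structure among miRNAs beyond the planted effects. Passing tests
therefore demonstrate the *self-consistency and statistical behaviour*
of the workflow under its own assumptions, not the clinical performance
of the panel on real sera.

## Numerical choices and degenerate inputs

* Strict inequalities at every threshold and at α on both sides; a
  p-value exactly equal to α satisfies neither requirement.
* Degenerate zero-variance t-tests: p = 1 / p = 0 with a flag, never NaN.
* Pair orientation tie-break: lexicographic miRNA id.
* Classifier distance ties: first class in declared order; non-finite
  features yield an explicit `unclassifiable` flag.
* Offset cancellation is exact in exact arithmetic; in floating point
  the screen's p-values move by < 10⁻¹² under ±3-cycle shifts
  (guaranteed < 10⁻⁹ by test).
* All randomness flows from `numpy.random.default_rng(seed)`; scenario
  sub-analyses in the acceptance script derive disjoint seed blocks from
  the one CLI seed.

## Problem sizes used by the test and acceptance runs

Chosen as the package's own working scale: 100-seed recovery runs of the
65-sample screening cohort, 200-seed runs of the null (40-sample) and
validation (144-sample) cohorts, 100-instance permutation enumerations
at 4 vs 4, and single 1887-probe arrays. A full run of the test suite
plus the acceptance script completes in well under a minute of CPU.

## Known limitations

* The "opposite trend" formalization and the nearest-centroid rule are
  package choices where the workflow's description is qualitative.
* The ceiling rule treats masked cells as uninformative rather than as
  censored-above; real non-amplifications are usually CT > 40 and would
  trip the ceiling if recorded.
* No multiple-testing correction by default (faithful to the screening
  design); the Bonferroni-minded should read the 10⁻⁴ stricter screen.
* GEO series-matrix support is a dialect reader for intensity tables,
  not a GEO API client; deposited-array count checks require the
  download and are not part of the desk-scale suite.
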