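# Methods

This note documents the models and procedures implemented in `chdpsn`,
the choices made where the design was genuinely open, and what the
synthetic world does and does not establish.

## Ontology similarity

The diagnosis space is a rooted hierarchy, possibly a DAG. Depth is
counted in nodes from the root (`depth(root) = 1`); on a DAG a term's
depth is the minimum over its parents plus one. Term similarity is the
Wu–Palmer measure `2·depth(LCA)/(depth(a)+depth(b))`, chosen because it
is depth-based, bounded in [0, 1], equals 1 exactly on identical terms in
a tree, and is the standard depth-based measure in the ontology
literature. The LCA on a DAG is the deepest common ancestor-or-self,
with a lexicographic term-id tie-break so results are deterministic.

Diagnosis *lists* are compared with a symmetric best-match average: each
term is matched to its most similar counterpart on the other side, the
two directional means are averaged, and the result is turned into a
distance. This construction is symmetric, bounded and zero on identical
term sets. In `grade` mode the primary ("basic") and secondary sub-lists
are compared separately and blended as `α·d_primary + (1−α)·d_secondary`
with α = 0.7 by default (primary diagnoses dominate but secondary
lesions still matter). Degenerate cases are resolved a priori: if either
record has no secondary terms, the primary part takes full weight (and
vice versa); if either record has no primary-flagged diagnosis at all,
the pair falls back to `ungrade`.

## Per-group distances and missingness

Echocardiographic indicators are structurally sparse — a measurement
exists only when the corresponding malformation does — so imputation
would fabricate anatomy. All per-group distances are therefore
Gower-style means of range-normalised absolute differences restricted to
features observed in **both** records, and a pair sharing no observed
feature gets the maximal distance 1. Zero-range features contribute 0
when equal and 1 otherwise. Scaling ranges are the training-cohort
min–max of each (transformed) feature; an index patient outside the
training range has its per-feature contribution clipped at 1.

One consequence worth knowing: because Gower normalises each column by
its range, any per-column affine transform leaves the distances
unchanged — so the `origin` and `zscore` preprocessings produce
*identical* distance matrices. They remain distinct preprocessings (the
z-scored feature table is what a local model sees, and the transform is
what an index patient is standardised with), and `combination` genuinely
changes the geometry by adding ratio columns computed only where both
members are observed (zero denominators yield missing, logged). The
z-score uses cohort-wide sample statistics (ddof = 1), not age- or
BSA-adjusted norms.

## Fusion and phase maps

The patient distance is the weighted sum of the four group distances
divided by the sum of the active weights. Division by the weight sum
(rather than cohort-relative min–max post-scaling) was chosen because it
keeps the result in [0, 1], makes it independent of the rest of the
cohort and of the index patient, and renders the fusion invariant to
rescaling all weights — so clinician-adjusted weights need no
normalisation. Per-group component matrices are cached so re-weighting
re-fuses without recomputing group distances. Phase maps zero the
weights of the groups unavailable at a clinical stage: screening uses
diagnoses only, echo adds indicators, patient adds preoperative clinical
features, and surgery uses all four.

## Neighbourhoods, votes and local models

KNN retrieval sorts by distance with an ascending patient-id tie-break
(deterministic); threshold retrieval keeps everyone within distance t
and may legitimately be empty — that is reported as an error for the
caller to widen, never silently relaxed. The binary vote is strict:
True only when **more than** 50% of the group had the outcome, so an
exact split votes False. The four ventilation classes use half-open bins
[0,12), [12,24), [24,48), [48,∞) hours — 48 h itself is class IV. The
multiclass vote takes the plurality class, ties resolved toward the
class more prevalent in the full training cohort, then by class order.

KNN+LR fits an L2-regularised logistic regression (C = 1.0, lbfgs,
multinomial for the 4-class task) on the group members only; small local
fits need shrinkage, hence the default regularisation. Features are the
transformed indicator columns plus clinical/surgical numerics and
0/1-encoded sex, mean-imputed and standardised with *training* cohort
statistics (the distance computations never see imputed values; the
imputation exists only because a linear model needs a complete matrix).
A single-class neighbourhood yields a constant-probability model, which
by construction agrees with the vote. k-Random+LR fits the same
estimator on a seeded uniform sample of equal size, excluding the index
patient. The index patient's outcome is never read anywhere on the
prediction path.

## Evaluation

Accuracy, recall, precision and F1 follow the standard confusion-count
definitions; undefined ratios (zero denominators) are reported as
undefined-with-reason rather than 0. AUC is the rank-based Mann-Whitney
statistic with mid-rank ties; the multiclass AUC is macro one-vs-rest
over the classes for which both sides are present (per-class values are
also available). The population-level k is selected by leave-one-out
neighbourhood voting on the training cohort over the grid
{3, 5, 10, 15, 20, 30, 50, 75, 100, 150, 200} ∩ [1, n−1], maximising F1
by default; because F1 favours the sharp labels of small neighbourhoods
while AUC rewards the finer score resolution of large ones, the
selection metric is exposed (`metric="f1"|"auc"`) and the AUC-based
choice is what the signal-recovery check uses. Ties go to the smallest
k. The benchmark grid mirrors the evaluation protocol: per task, six
KNN-vote rows and six KNN+LR rows ({origin, zscore, combination} ×
{grade, ungrade}) plus one k-Random+LR baseline row, which is size-matched
to the first configuration's optimized k. The vote's ROC score is the
neighbour outcome proportion. Group contrasts use the two-sided
Mann-Whitney U (exact enumeration when both sides have ≤ 8 cases,
otherwise the tie-corrected normal approximation) for continuous
outcomes and the 1-df Pearson χ² (Yates correction optional) for binary
ones, flagged at 0.05.

## Map view

t-SNE embeds the precomputed fused distance matrix (perplexity 30,
capped at (n−1)/3; 1000 iterations). Each point's initial position is
derived from a hash of its patient id and the seed, so the layout does
not depend on the order of the cohort file; exact coordinates are still
floating-point sensitive, so order invariance is structural (which
cluster a patient lands in), not bitwise, and is tested as such.

## The synthetic world

The generator emulates a paediatric surgical CHD cohort: lesion labels
from a mixture (ASD+VSD 34.8%, VSD 31.9%, ASD 25.7%, PFO 2.8%, PDA 2.6%,
other complex lesions 2.2%), demographics anchored at the emulated
cohort's medians (age 12 months, height 75 cm, weight 9.2 kg, SpO₂ 98%,
surgery 119 min, CPB 60 min, clamp 40 min), and a latent severity score
(standard normal shifted per lesion) that jointly drives indicator
values, operative times and outcomes — the minimal structure under which
"similar patients have similar outcomes", the premise of a PSN. The
complication intercept and the ventilation intercept are solved by
quadrature over the lesion mixture so the population rates hit 25.7%
complications and 63% in the shortest ventilation bin regardless of the
signal slopes (b = 2.0 on the complication logit, d = 0.8 on
log-ventilation-hours by default; b = d = 0 gives the no-signal null).
Indicators are emitted only for lesions present in the diagnosis list,
with 5% additional uniform dropout; schema ranges are wide enough that
default-noise emissions always pass the quality filter. The default
scale is n = 1000 to keep runtimes low; n is a spec field.

What a green test on this world establishes: that the implementation
recovers planted neighbourhood-local signal and orders KNN+LR above the
random baseline, and that it returns to chance under the null. What it
does not establish: performance on real cohorts — the generator has no
measurement error correlated with severity, no informative missingness
beyond lesion structure, no site or era effects, and far fewer
indicators (about 20) than a real echo report schema.

## Known limitations

* The per-group distance forms and the grade-mode weighting are
  documented package choices; alternative forms from the original
  clinical deployments of this idea are not distinguishable from the
  outside and the formula surface is pluggable.
* Weights are user-set, never learned.
* The χ² test is applied regardless of expected-count size; for very
  small groups the Mann-Whitney exact path is the reliable one.
* t-SNE determinism is guaranteed for a fixed seed and cohort; only
  structural layout properties are guaranteed under reordering.
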