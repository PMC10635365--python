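# Methods

## Problem and approach

Supervised models that predict whether a drug pair acts synergistically
on a cancer cell line are limited by the size of public synergy screens
(thousands of measured combinations against a chemical space of
millions).  This package implements a data-augmentation protocol that
expands a synergy dataset by *compound substitution*: one drug of a
measured pair is replaced by another compound with highly similar
pharmacology, and the new pair inherits the measured cell line and
synergy score.  The substitution is guided by a composite similarity
score and validated by rank-correlation of potency profiles.

## Similarity metrics

Three pairwise metrics are computed for drugs *i*, *j*:

* **TC** — Tanimoto coefficient `|FP_i & FP_j| / |FP_i | FP_j|` between
  binary path-based molecular fingerprints.  The built-in generator is
  RDKit's hashed linear-path fingerprint (paths of 1–7 bonds, 1024 bits),
  the same family as Open Babel's FP2; any fixed-length binary
  fingerprint can be supplied instead, as the method only requires one
  consistent fingerprint per library.  Two all-zero fingerprints score 0.
* **MCC** — Matthews correlation coefficient over the 2×2 contingency of
  target proteins within a fixed protein universe: T targeted by both,
  A / B by only one drug, N by neither,

      MCC = (T·N − A·B) / √((T+A)(T+B)(N+A)(N+B)).

  A zero marginal (a drug with no targets, or targeting the whole
  universe) leaves the ratio undefined and is reported as 0, the neutral
  no-evidence value.
* **τ-b** — Kendall rank correlation with tie correction between the two
  drugs' pIC50 monotherapy profiles over their shared cell lines,

      τ_b = (n_c − n_d) / √((n_c + n_d + n_1)(n_c + n_d + n_2)),

  computed from exact integer concordance counts (concordant n_c,
  discordant n_d, tied-in-one-list n_1 / n_2).  Fewer than two shared
  cell lines, or a constant list (zero denominator), yield exactly 0:
  "no information", not "no correlation".  Ties in pIC50 are exact
  equality of the parsed input values; no epsilon is applied, because the
  inputs are data rather than computed quantities.

TC and MCC combine into the drug action/chemical similarity score

    DACS = √(TC² + max(MCC, 0)²) ∈ [0, √2],

with negative MCC clamped to zero so that anti-correlated target sets are
treated as absence of mechanistic evidence.  τ-b is *not* part of DACS;
it is the independent pharmacological read-out used to decide how high a
DACS cutoff must be before substitution is trustworthy.

## Cutoff selection

Two curves are swept over a DACS threshold grid (default 0 to 1.42 in
steps of 0.01, inclusive `metric ≥ threshold` comparison):

1. the fraction of drug pairs with strictly positive τ-b among pairs at
   or above the threshold (undefined — NaN, not 0 — when no pair
   qualifies, to avoid fabricating a trend at high thresholds);
2. the number of distinct candidate compounds whose best DACS against
   any library drug clears the threshold (each candidate counted once).

The count curve is min-max normalized to [0, 1] (the two curves have
different units; the normalization maps the observed maximum to 1 and
minimum to 0 exactly) and the operating cutoff is the crossing of the
two curves, linearly interpolated between grid points; with several
crossings the highest threshold wins, favouring substitution fidelity
over yield.  A flat count curve normalizes to the constant 1.  If no
crossing exists in the grid an explicit no-crossing result is returned.

## Augmentation

Given a cutoff, every library drug receives the list of candidates with
`DACS ≥ cutoff` (descending DACS, ties broken by identifier; a candidate
is never a substitute for itself).  Each original instance then spawns
one new instance per substitute per position — position a, then b, one
replacement at a time, never both — inheriting the parent's cell line and
synergy score.  Generated pairs that collapse onto the partner drug are
dropped; duplicates on the (canonical pair, cell line) key keep the first
occurrence, with measured originals always winning over generated rows
(conflicting duplicate scores are logged).  The augmented output is a
superset containing the originals.  Cell lines are never altered, so the
tissue composition of the dataset is invariant under augmentation.  The
optional assay-quality score is carried through unchanged and never used
for filtering.

Labeling thresholds the synergy score: `score ≥ 20` synergistic,
`score ≤ −20` antagonistic, the ambiguous middle excluded (inclusive
boundaries).

## Evaluation protocol

A pair on a cell line is represented by a 900-dimensional vector: two
300-dimensional drug embeddings in canonical (lexicographic) pair order
plus a 300-dimensional cell embedding.  Embedders are pluggable; the
built-in baselines are deterministic so every experiment is exactly
reproducible:

* drugs — the 1024-bit fingerprint folded by index hashing (component
  *j* counts the set bits at positions `i ≡ j mod 300`);
* cells — a seeded Gaussian random projection of the gene-expression
  column, scaled by `1/√n_genes`.

Learned chemistry and expression embedders can be dropped in through the
same interface; the baselines are intentionally simple, structure-
preserving encoders, not approximations of any particular learned model.

Two 5-fold cross-validation schemes are provided: seeded stratified
random folds (class proportions preserved to within one instance per
fold), and tissue-based folds in which each fold is one tissue group
(breast, digestive, excretory, respiratory, other — the mapping is an
input file, not a hardcoded list), so no tissue appears on both sides of
a split.  In the augmented condition the training folds' original
instances are topped up with augmented instances derived **only from
training-fold parents**, added greedily so the synergistic:antagonistic
ratio of the additions tracks the training set's ratio (a one-sided pool
is drawn down only as far as the ratio tolerates, with the shortfall
reported).  Validation is always on original instances; an augmented
training instance tracing to a validation parent raises a hard
`LeakageError`.  This parent-tracking discipline is applied in the
random-split scheme as well, where instance-level leakage is otherwise
silent.

Classifiers are scikit-learn ensembles behind a small configuration
interface.  Defaults: Random Forest with 300 trees, `min_samples_leaf`
85, √-features per split, balanced class weights; Gradient Boosting
with 650 stages, `min_samples_leaf` 120, √-features per split, learning
rate 0.28, depth 5.  The metric panel per fold is ACC, TPR, FPR, PPV,
AUC (from the continuous classifier score), MCC and F1, with the
synergistic class positive; aggregates are fold means (NaN-aware: a
one-class validation fold has no AUC).  No reverse-order pair
duplication is performed; the canonical pair order makes orientation a
non-feature.

## Synthetic cohorts

The generator produces the six input tables with an explicit latent
cluster structure so that every stage is testable without downloads:

* drugs in the same cluster share fingerprint bits and target proteins
  at configurable overlap rates (defaults 0.9/0.9), with the remainder
  private and random;
* candidate substitutes belong to the same clusters but with a
  per-candidate strength factor drawn from [0.55, 1.0], giving the
  continuum of substitute quality a real compound database shows — this
  is what makes the substitute-count curve decrease smoothly and the
  curve crossing well-defined;
* pIC50 profiles are a shared cluster response (mean 6, sd 1 across
  cells) plus Gaussian noise (default sd 0.3 pIC50 units);
* expression is a tissue-level mean profile plus per-cell noise; cells
  are spread round-robin over the five tissue groups;
* the synergy score of an instance is a latent surface over (cluster
  pair, tissue) plus measurement noise, and augmented instances inherit
  their parents' *measured* (noisy) scores, as the protocol prescribes.

Default scale: 12 clusters × 4 drugs, 40 candidates, 25 cell lines in 5
tissue groups, 900 instances, 200 genes.  The synergy-surface parameters
(pair effect sd 25 around mean +10, tissue interaction sd 20,
measurement noise sd 15) were chosen so the cohort reproduces the
difficulty regime reported for real tissue-held-out synergy prediction:
a tissue-CV baseline AUC around 0.6–0.75 and roughly 70% synergistic
prevalence among labeled instances.  Low-noise variants of earlier
designs made the task nearly saturating (baseline AUC ≈ 0.9), which no
published tissue-held-out evaluation resembles.

All randomness flows from a single spec seed through named
`SeedSequence` child streams, so each table is individually reproducible
regardless of how the others are consumed.  A hand-written micro-cohort
(`worked_fixture`, 6 drugs / 3 cells / 4 instances, no RNG) anchors the
test suite: every similarity value, substitute list and augmented
instance is verified against paper-and-pencil enumeration.

### What the cohorts do and do not emulate

The generator reproduces the *structural* assumptions of the method —
clustered chemistry with shared targets, correlated potency rankings
within clusters, tissue-structured cells, score inheritance — but not
the marginal distributions of any real screen: fingerprints are random
bit sets rather than real molecules, expression is isotropic Gaussian
around tissue means, and the synergy surface is piecewise-constant per
cluster pair.  Passing tests therefore demonstrate the correctness and
internal consistency of the pipeline and the direction of the
augmentation effect under the stated assumptions, not performance on
real chemical matter.

## Desk-scale evaluation settings

On synthetic cohorts the classifier stage runs with the published
hyperparameters except `n_estimators=200` for both models (runtime; the
override is recorded in every report).  `min_samples_leaf` deliberately
stays at 85/120: a fixed *absolute* leaf size is the mechanism that
makes augmentation matter in this protocol — it constrains a model
trained on a few hundred original instances severely while barely
constraining one trained on the several-thousand-instance augmented
set, so the augmented model can resolve finer structure at identical
settings.  Scaling the leaf size down proportionally for small cohorts
(e.g. to 3–5) removes that mechanism and with it the measurable benefit,
so it is not done here.

## Numerical choices

* τ-b and MCC are computed from exact integer counts; 5-element perfect
  concordance returns exactly 1.0.
* Canonical pair order (lexicographic by identifier) is applied wherever
  pairs are stored or embedded.
* Threshold comparisons are inclusive (`≥`), making √2 attainable by
  identical drugs.
* "Positive τ" always means strictly `τ > 0`; τ = 0 encodes missing
  information and never counts as positive.
* TSV output uses fixed 6-decimal formatting so reruns diff clean; every
  output carries a provenance header with version and seed.

## Known limitations

* The fingerprint baseline is path-based only; 3-D, pharmacophore, or
  learned chemical similarity is out of scope (the embedder interface
  accepts them).
* The protein universe is a flat set; no network propagation over the
  interactome is performed.
* Inherited scores are the parents' measurements; no re-estimation of
  synergy for substituted pairs is attempted — that is the protocol's
  central approximation, and its validity degrades as the DACS cutoff
  decreases (the test suite asserts this trend on synthetic truth).
* The directional-benefit result is stochastic by nature: individual
  seeds can show no improvement, particularly for the Random Forest,
  and the tests assert a majority-of-seeds direction rather than a
  per-seed guarantee.
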