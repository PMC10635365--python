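# dacsaug

Drug-synergy dataset augmentation by DACS-guided compound substitution.

Machine-learning models that predict synergistic anticancer drug
combinations are starved for training data: public screens measure
thousands of combinations, while the space of plausible pairs is in the
millions.  `dacsaug` implements an augmentation protocol for researchers
working with such screens.  It expands a synergy dataset by replacing
one drug of a measured pair with a pharmacologically equivalent
compound, letting the new pair inherit the measured cell line and
synergy score, and then evaluates — with strictly leakage-free
cross-validation — whether classifiers trained on the expanded data
generalize better.

The substitution is guided by the **drug action/chemical similarity
(DACS)** score

```
DACS(i, j) = sqrt( TC(i, j)^2 + max(MCC(i, j), 0)^2 )  in  [0, sqrt(2)]
```

where TC is the Tanimoto coefficient between path-based molecular
fingerprints and MCC is the Matthews correlation coefficient between
the two drugs' target-protein sets within a fixed protein universe.
Whether a DACS level is *high enough* is decided empirically from a
third, independent metric: the Kendall τ-b rank correlation between the
two drugs' pIC50 monotherapy profiles over shared cell lines.  The
operating cutoff is the crossing point of two curves over the DACS
threshold — the fraction of drug pairs with positively correlated
potency profiles (rising) and the min-max-normalized number of available
substitute compounds (falling).

The package provides, as both a Python library and a `dacsaug` command
line:

* the three similarity metrics and the all-vs-all pair table
  (`similarity`),
* threshold curves, the TC×MCC heatmap, and optimal-cutoff selection
  (`threshold`),
* substitution-based augmentation, labeling (synergistic ≥ 20,
  antagonistic ≤ −20), and class-ratio-preserving training-set
  expansion (`augmentation`),
* 900-dimensional feature assembly, random-stratified and tissue-based
  5-fold cross-validation with augmented-train/original-validate
  discipline, and RF/GBT evaluation (`evaluation`),
* a synthetic cohort generator with latent cluster ground truth, so the
  whole pipeline runs and is testable without any downloads
  (`synthetic`),
* TSV/JSON readers and writers for all formats (`io_tables`).

See `docs/methods.md` for the model, its assumptions, and all numerical
conventions.

## Worked example

Run the full pipeline on a synthetic cohort at the default scale
(48 library drugs in 12 latent clusters, 40 candidate substitutes,
25 cell lines in 5 tissue groups, 900 synergy instances):

```python
from dacsaug import *
from dacsaug.threshold import default_grid

cohort = generate_cohort(CohortSpec(seed=1))
pairs = pairwise_similarity_table(
    list(cohort.originals), cohort.profiles, cohort.universe)
grid = default_grid()
cut = select_optimal_cutoff(
    threshold_curve(pairs, "dacs", grid),
    substitute_count_curve(list(cohort.originals), list(cohort.candidates),
                           cohort.profiles, cohort.universe, grid))
subs = build_substitute_map(
    list(cohort.originals), list(cohort.candidates),
    cohort.profiles, cohort.universe, cut.dacs_cutoff)
expanded = augment_dataset(list(cohort.instances), subs)
```

This prints, via the summaries in the library:

```
pairs: 1128
cutoff: 0.50  fraction: 1.00  substitutes: 40
original: 900 instances, synergy 11.5 +/- 36.4
augmented: 6421 instances, synergy 12.7 +/- 36.0
labeled: 2588 synergistic + 1187 antagonistic = 3775
```

Reading: the 48-drug library yields C(48,2) = 1128 pairs; the two
curves cross at a DACS cutoff of 0.50, where all qualifying pairs have
positively correlated potency rankings and all 40 candidates remain
usable; substitution expands 900 instances to 6421, and — the key sanity
check — the synergy-score distribution of the augmented set (12.7 ± 36.0)
stays close to the original's (11.5 ± 36.4), so augmentation does not
bias the dataset toward synergism or antagonism.

The same pipeline from the shell:

```
dacsaug simulate --out data --seed 1
dacsaug similarity --structures data/structures.tsv --targets data/targets.tsv \
        --monotherapy data/monotherapy.tsv --out pairs.tsv
dacsaug curves --pairs pairs.tsv --metric dacs --out frac.tsv \
        --synergy data/synergy.tsv --structures data/structures.tsv \
        --targets data/targets.tsv --monotherapy data/monotherapy.tsv \
        --count-out count.tsv
dacsaug cutoff --fraction-curve frac.tsv --count-curve count.tsv --out cutoff.json
dacsaug augment --synergy data/synergy.tsv --structures data/structures.tsv \
        --targets data/targets.tsv --monotherapy data/monotherapy.tsv \
        --cutoff 0.50 --out augmented.tsv
dacsaug label --synergy augmented.tsv --out labeled_aug.tsv
dacsaug label --synergy data/synergy.tsv --out labeled.tsv
dacsaug split --labeled labeled.tsv --scheme tissue \
        --cell-meta data/cell_meta.tsv --out folds.tsv
dacsaug evaluate --labeled labeled.tsv --augmented-labeled labeled_aug.tsv \
        --folds folds.tsv --structures data/structures.tsv \
        --expression data/expression.tsv --classifier GBT \
        --condition augmented --override n_estimators=200 --out eval_gbt
```

Real data drop in through the same six TSV formats (synergy instances,
monotherapy pIC50s, drug–target associations with an optional confidence
filter, SMILES or fingerprint structures, a gene-expression matrix, and
cell-line tissue metadata); see the `io_tables` module docstring for the
column conventions.

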