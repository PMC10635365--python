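"""Feature assembly, cross-validation protocols, and tree-ensemble evaluation.

A drug pair on a cell line is represented by a 900-dimensional vector:
two 300-dimensional drug embeddings (canonical pair order) concatenated
with a 300-dimensional cell-line embedding of its gene-expression
profile.  Embedders are pluggable; the built-in baselines are a
deterministic fingerprint fold for drugs and a seeded Gaussian random
projection for expression profiles.

Two 5-fold cross-validation protocols are provided: a stratified random
split, and a tissue-based split in which each fold is one tissue group
(breast, digestive, excretory, respiratory, other) so that no tissue
appears on both sides.  In the augmented condition the training folds'
original instances are topped up with augmented instances derived only
from those same training parents — validation is always on original
instances, and any augmented instance tracing to a validation parent is
a hard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .augmentation import (
    SYNERGISTIC,
    LabeledInstance,
    ratio_preserving_augment,
)
from .errors import LeakageError, ValidationError
from .similarity import DrugRecord

__all__ = [
    "EMBED_DIM",
    "FEATURE_DIM",
    "fold_fingerprint",
    "GaussianProjection",
    "embed_drug",
    "embed_cell",
    "FeatureBuilder",
    "FoldAssignment",
    "make_folds",
    "ClassifierConfig",
    "classifier_config",
    "classification_metrics",
    "EvalReport",
    "run_cv",
]

EMBED_DIM = 300
FEATURE_DIM = 3 * EMBED_DIM

METRIC_NAMES = ("ACC", "TPR", "FPR", "PPV", "AUC", "MCC", "F1")


# ---------------------------------------------------------------------------
# embeddings


def fold_fingerprint(fp: np.ndarray, dim: int = EMBED_DIM) -> np.ndarray:
    """Fold a binary fingerprint into `dim` dimensions by index hashing.

    Component j is the number of set bits at positions i with i % dim == j.
    """
    fp = np.asarray(fp, dtype=bool)
    out = np.zeros(dim, dtype=float)
    np.add.at(out, np.arange(fp.size) % dim, fp.astype(float))
    return out


def embed_drug(
    record: DrugRecord,
    embedder: Optional[Callable[[DrugRecord], np.ndarray]] = None,
) -> np.ndarray:
    """300-dimensional drug embedding (default: fingerprint index fold)."""
    if embedder is None:
        vec = fold_fingerprint(record.fingerprint)
    else:
        vec = np.asarray(embedder(record), dtype=float)
    if vec.shape != (EMBED_DIM,):
        raise ValidationError(
            f"drug embedder returned shape {vec.shape}, expected ({EMBED_DIM},)"
        )
    return vec


class GaussianProjection:
    """Seeded Gaussian random projection of expression profiles.

    The projection matrix has shape (n_genes, dim); a unit basis input
    returns the corresponding matrix row, and the same seed always
    rebuilds the same matrix.
    """

    def __init__(self, n_genes: int, dim: int = EMBED_DIM, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.matrix = rng.standard_normal((n_genes, dim)) / math.sqrt(n_genes)
        self.seed = seed

    def __call__(self, column: np.ndarray) -> np.ndarray:
        x = np.asarray(column, dtype=float)
        if x.shape != (self.matrix.shape[0],):
            raise ValidationError(
                f"expression column of length {x.shape}, expected "
                f"({self.matrix.shape[0]},)"
            )
        return x @ self.matrix


def embed_cell(
    column: np.ndarray,
    embedder: Callable[[np.ndarray], np.ndarray],
) -> np.ndarray:
    """300-dimensional cell-line embedding of one expression column."""
    vec = np.asarray(embedder(column), dtype=float)
    if vec.shape != (EMBED_DIM,):
        raise ValidationError(
            f"cell embedder returned shape {vec.shape}, expected ({EMBED_DIM},)"
        )
    return vec


@dataclass
class FeatureBuilder:
    """Assemble 900-dimensional feature vectors for synergy instances.

    Drug and cell embeddings are computed once per identifier and cached;
    the drug order inside a vector follows the instance's canonical pair
    order.
    """

    drug_records: Mapping[str, DrugRecord]
    expression: pd.DataFrame  # genes x cell lines
    cell_embedder: Optional[Callable[[np.ndarray], np.ndarray]] = None
    drug_embedder: Optional[Callable[[DrugRecord], np.ndarray]] = None
    projection_seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_embedder is None:
            self.cell_embedder = GaussianProjection(
                n_genes=self.expression.shape[0], seed=self.projection_seed
            )
        self._drug_cache: dict[str, np.ndarray] = {}
        self._cell_cache: dict[str, np.ndarray] = {}

    def _drug_vec(self, drug_id: str) -> np.ndarray:
        if drug_id not in self._drug_cache:
            try:
                record = self.drug_records[drug_id]
            except KeyError:
                raise ValidationError(f"no drug record for {drug_id!r}") from None
            self._drug_cache[drug_id] = embed_drug(record, self.drug_embedder)
        return self._drug_cache[drug_id]

    def _cell_vec(self, cell: str) -> np.ndarray:
        if cell not in self._cell_cache:
            if cell not in self.expression.columns:
                raise ValidationError(f"no expression profile for cell {cell!r}")
            column = self.expression[cell].to_numpy(dtype=float)
            self._cell_cache[cell] = embed_cell(column, self.cell_embedder)
        return self._cell_cache[cell]

    def features(self, instances: Sequence[LabeledInstance]) -> np.ndarray:
        out = np.empty((len(instances), FEATURE_DIM), dtype=float)
        for i, inst in enumerate(instances):
            out[i, :EMBED_DIM] = self._drug_vec(inst.drug_a)
            out[i, EMBED_DIM : 2 * EMBED_DIM] = self._drug_vec(inst.drug_b)
            out[i, 2 * EMBED_DIM :] = self._cell_vec(inst.cell_line)
        return out


# ---------------------------------------------------------------------------
# folds

SCHEMES = ("random_stratified", "tissue")


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index (0-based) per instance, aligned with the instance list."""

    fold_ids: np.ndarray
    scheme: str
    n_folds: int
    groups: Optional[tuple[str, ...]] = None  # tissue names when scheme="tissue"


def make_folds(
    instances: Sequence[LabeledInstance],
    scheme: str,
    cell_tissue: Optional[Mapping[str, str]] = None,
    tissue_groups: Optional[Sequence[str]] = None,
    seed: int = 0,
    n_folds: int = 5,
) -> FoldAssignment:
    """Assign original labeled instances to cross-validation folds.

    random_stratified: seeded stratified k-fold preserving the class
    proportion in each fold to within one instance.  tissue: each fold is
    one tissue group, in the order given by `tissue_groups`; every cell
    line must be mapped.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    labels = np.array([inst.label == SYNERGISTIC for inst in instances], dtype=int)
    if scheme == "random_stratified":
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_ids = np.empty(len(instances), dtype=np.int64)
        for k, (_, val_idx) in enumerate(skf.split(np.zeros(len(instances)), labels)):
            fold_ids[val_idx] = k
        return FoldAssignment(fold_ids=fold_ids, scheme=scheme, n_folds=n_folds)
    if cell_tissue is None or tissue_groups is None:
        raise ValidationError("tissue scheme needs cell_tissue and tissue_groups")
    groups = tuple(tissue_groups)
    index = {t: k for k, t in enumerate(groups)}
    fold_ids = np.empty(len(instances), dtype=np.int64)
    for i, inst in enumerate(instances):
        tissue = cell_tissue.get(inst.cell_line)
        if tissue is None:
            raise ValidationError(f"cell line {inst.cell_line!r} has no tissue mapping")
        if tissue not in index:
            raise ValidationError(
                f"tissue {tissue!r} of cell {inst.cell_line!r} not in groups {groups}"
            )
        fold_ids[i] = index[tissue]
    return FoldAssignment(
        fold_ids=fold_ids, scheme=scheme, n_folds=len(groups), groups=groups
    )


# ---------------------------------------------------------------------------
# classifiers

_RF_DEFAULTS = {
    "n_estimators": 300,
    "min_samples_leaf": 85,
    "max_features": "sqrt",
    "class_weight": "balanced",
}
_GBT_DEFAULTS = {
    "n_estimators": 650,
    "min_samples_leaf": 120,
    "max_features": "sqrt",
    "learning_rate": 0.28,
    "max_depth": 5,
}


@dataclass(frozen=True)
class ClassifierConfig:
    """A named tree-ensemble configuration with recorded overrides."""

    name: str
    params: Mapping[str, object]
    overrides: Mapping[str, object]

    def make(self, random_state: int):
        cls = RandomForestClassifier if self.name == "RF" else GradientBoostingClassifier
        return cls(random_state=random_state, **dict(self.params))


def classifier_config(name: str, **overrides: object) -> ClassifierConfig:
    """Default RF / GBT settings, overridable for small-cohort runs.

    RF: 300 trees, min leaf 85, sqrt features per split, balanced class
    weights.  GBT: 650 boosting stages, min leaf 120, sqrt features per
    split, learning rate 0.28, max depth 5.  The defaults target
    full-scale datasets; the deep min-leaf values are degenerate on small
    cohorts, where overrides such as min_samples_leaf=3 are appropriate
    (and are recorded in the report).
    """
    if name == "RF":
        params = dict(_RF_DEFAULTS)
    elif name == "GBT":
        params = dict(_GBT_DEFAULTS)
    else:
        raise ValidationError(f"unknown classifier {name!r}; expected RF or GBT")
    params.update(overrides)
    return ClassifierConfig(name=name, params=params, overrides=dict(overrides))


# ---------------------------------------------------------------------------
# metrics and cross-validation


def classification_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, y_score: np.ndarray
) -> dict[str, float]:
    """Binary panel: ACC, TPR, FPR, PPV, AUC, MCC, F1 (positive = synergistic).

    Rates whose denominator is empty, and AUC on a one-class validation
    set, are reported as NaN.
    """
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()

    def _ratio(num: float, den: float) -> float:
        return num / den if den else float("nan")

    tpr = _ratio(tp, tp + fn)
    fpr = _ratio(fp, fp + tn)
    ppv = _ratio(tp, tp + fp)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den else float("nan")
    auc = (
        float(roc_auc_score(y_true, y_score))
        if len(np.unique(y_true)) == 2
        else float("nan")
    )
    return {
        "ACC": _ratio(tp + tn, tp + tn + fp + fn),
        "TPR": tpr,
        "FPR": fpr,
        "PPV": ppv,
        "AUC": auc,
        "MCC": mcc,
        "F1": f1,
    }


@dataclass(frozen=True)
class EvalReport:
    """Per-fold and aggregate classification metrics for one CV run."""

    classifier: str
    condition: str
    scheme: str
    seed: int
    per_fold: tuple[dict, ...]
    aggregate: dict
    overrides: Mapping[str, object]

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(fold=row["fold"], **{m: row[m] for m in METRIC_NAMES})
                for row in self.per_fold]
        rows.append(dict(fold="mean", **{m: self.aggregate[m] for m in METRIC_NAMES}))
        df = pd.DataFrame(rows)
        df.insert(0, "classifier", self.classifier)
        df.insert(1, "condition", self.condition)
        df.insert(2, "scheme", self.scheme)
        return df


def _labels(instances: Sequence[LabeledInstance]) -> np.ndarray:
    return np.array([int(i.label == SYNERGISTIC) for i in instances], dtype=int)


def run_cv(
    folds: FoldAssignment,
    original_labeled: Sequence[LabeledInstance],
    augmented_pool: Sequence[LabeledInstance],
    config: ClassifierConfig,
    condition: str,
    feature_builder: FeatureBuilder,
    seed: int = 0,
) -> EvalReport:
    """Cross-validate with augmented-train / original-validate discipline.

    Per fold the training set is the original instances of the other
    folds; under condition="augmented" it is topped up with
    ratio-preserving augmented instances derived only from those training
    parents.  Validation is always the held-out fold's original
    instances, with synergistic as the positive class.  AUC comes from
    the classifier's continuous score.
    """
    if condition not in ("original", "augmented"):
        raise ValidationError(f"unknown condition {condition!r}")
    if folds.fold_ids.shape[0] != len(original_labeled):
        raise ValidationError("fold assignment does not align with the instances")
    parent_of = {p.instance_id: p.parent_id for p in augmented_pool}
    per_fold: list[dict] = []
    for k in range(folds.n_folds):
        val_mask = folds.fold_ids == k
        val = [inst for inst, m in zip(original_labeled, val_mask) if m]
        train = [inst for inst, m in zip(original_labeled, val_mask) if not m]
        if not val or not train:
            raise ValidationError(f"fold {k} leaves an empty train or validation set")
        n_added = 0
        if condition == "augmented":
            train_ids = {t.instance_id for t in train}
            val_ids = {v.instance_id for v in val}
            pool_k = [p for p in augmented_pool if p.parent_id in train_ids]
            train, report = ratio_preserving_augment(
                [t for t in train], pool_k, seed=seed * folds.n_folds + k
            )
            n_added = report.added_synergistic + report.added_antagonistic
            for inst in train:
                if inst.provenance == "augmented" and (
                    inst.parent_id in val_ids or parent_of[inst.instance_id] in val_ids
                ):
                    raise LeakageError(
                        f"augmented instance {inst.instance_id!r} traces to a "
                        f"validation-fold parent in fold {k}"
                    )
        y_train = _labels(train)
        if len(np.unique(y_train)) < 2:
            raise ValidationError(
                f"fold {k}: training set contains a single class; the cohort "
                "is too small or the labeling cutoffs too strict"
            )
        model = config.make(random_state=seed)
        x_train = feature_builder.features(train)
        x_val = feature_builder.features(val)
        model.fit(x_train, y_train)
        scores = model.predict_proba(x_val)[:, 1]
        preds = (scores >= 0.5).astype(int)
        row = classification_metrics(_labels(val), preds, scores)
        row.update(fold=k, n_train=len(train), n_val=len(val), n_added=n_added)
        per_fold.append(row)
    aggregate = {}
    for m in METRIC_NAMES:
        values = [row[m] for row in per_fold if not math.isnan(row[m])]
        aggregate[m] = float(np.mean(values)) if values else float("nan")
    return EvalReport(
        classifier=config.name,
        condition=condition,
        scheme=folds.scheme,
        seed=seed,
        per_fold=tuple(per_fold),
        aggregate=aggregate,
        overrides=config.overrides,
    )
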