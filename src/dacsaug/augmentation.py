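"""Substitution-based augmentation of a drug-synergy dataset.

An original synergy instance is a drug pair tested on a cell line with a
measured synergy score.  Augmentation replaces one drug of the pair (one
position at a time, never both) with a candidate compound whose DACS
similarity to the replaced drug clears a cutoff; the new instance
inherits the parent's cell line and synergy score.  Labeled
classification datasets are then derived by thresholding the score
(>= 20 synergistic, <= -20 antagonistic, ambiguous scores dropped).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .similarity import (
    DACS_MAX,
    DrugRecord,
    MonotherapyProfile,
    pair_similarity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SynergyInstance",
    "SubstituteMap",
    "LabeledInstance",
    "LabelReport",
    "AugmentationReport",
    "DistributionSummary",
    "build_substitute_map",
    "augment_dataset",
    "label_instances",
    "ratio_preserving_augment",
    "synergy_distribution_summary",
]

SYNERGISTIC = "synergistic"
ANTAGONISTIC = "antagonistic"


def canonical_pair(drug_a: str, drug_b: str) -> tuple[str, str]:
    return (drug_a, drug_b) if drug_a <= drug_b else (drug_b, drug_a)


@dataclass(frozen=True, kw_only=True)
class SynergyInstance:
    """One (drug pair, cell line, synergy score) record with provenance."""

    instance_id: str
    drug_a: str
    drug_b: str
    cell_line: str
    synergy_score: float
    qa_score: Optional[float] = None
    provenance: str = "original"
    parent_id: Optional[str] = None
    substituted_position: str = "none"

    def __post_init__(self) -> None:
        a, b = canonical_pair(self.drug_a, self.drug_b)
        object.__setattr__(self, "drug_a", a)
        object.__setattr__(self, "drug_b", b)
        if self.drug_a == self.drug_b:
            raise ValidationError(
                f"instance {self.instance_id!r}: drug paired with itself"
            )
        if not math.isfinite(self.synergy_score):
            raise ValidationError(f"instance {self.instance_id!r}: non-finite score")
        if self.provenance not in ("original", "augmented"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if (self.parent_id is not None) != (self.provenance == "augmented"):
            raise ValidationError("parent_id is set iff provenance is 'augmented'")
        if self.qa_score is not None and not (-3.0 <= self.qa_score <= 1.0):
            raise ValidationError(f"qa_score outside [-3, 1]: {self.qa_score}")
        if self.substituted_position not in ("a", "b", "none"):
            raise ValidationError(
                f"unknown substituted_position {self.substituted_position!r}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b)


@dataclass(frozen=True, kw_only=True)
class LabeledInstance(SynergyInstance):
    """A synergy instance with its binary class label."""

    label: str

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.label not in (SYNERGISTIC, ANTAGONISTIC):
            raise ValidationError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class SubstituteMap:
    """Per original drug: candidate substitutes with DACS >= cutoff,
    sorted by descending DACS then candidate id."""

    cutoff: float
    substitutes: Mapping[str, tuple[tuple[str, float], ...]]

    def for_drug(self, drug_id: str) -> tuple[tuple[str, float], ...]:
        return self.substitutes.get(drug_id, ())

    @property
    def n_distinct_candidates(self) -> int:
        return len({c for subs in self.substitutes.values() for c, _ in subs})


def build_substitute_map(
    originals: Sequence[DrugRecord],
    candidates: Sequence[DrugRecord],
    profiles: Mapping[str, MonotherapyProfile],
    universe: Iterable[str],
    cutoff: float,
) -> SubstituteMap:
    """DACS-screen every candidate against every original drug.

    Candidates without a fingerprint are skipped with a warning; a
    candidate with the same identifier as its original is never its own
    substitute.
    """
    if not (0.0 <= cutoff <= DACS_MAX):
        raise ValidationError(f"cutoff outside [0, sqrt(2)]: {cutoff}")
    uni = frozenset(universe)
    usable: list[DrugRecord] = []
    for cand in candidates:
        if cand.fingerprint.size == 0:
            logger.warning("candidate %s lacks a fingerprint; skipped", cand.drug_id)
            continue
        usable.append(cand)
    table: dict[str, tuple[tuple[str, float], ...]] = {}
    for orig in originals:
        hits: list[tuple[str, float]] = []
        for cand in usable:
            if cand.drug_id == orig.drug_id:
                continue
            score = pair_similarity(orig, cand, profiles, uni).dacs
            if score >= cutoff:
                hits.append((cand.drug_id, score))
        hits.sort(key=lambda item: (-item[1], item[0]))
        table[orig.drug_id] = tuple(hits)
    return SubstituteMap(cutoff=cutoff, substitutes=table)


def augment_dataset(
    instances: Sequence[SynergyInstance], subs: SubstituteMap
) -> list[SynergyInstance]:
    """Expand a synergy dataset by one-position compound substitution.

    For each original instance and each position (a, then b), every
    substitute of the drug at that position spawns one new instance
    carrying the parent's cell line and synergy score.  Generated
    instances whose substitute collides with the partner drug are
    dropped; duplicates on the (canonical pair, cell line) key keep the
    first occurrence, with originals always winning over generated rows.
    The returned list is the originals followed by the generated rows.
    """
    for inst in instances:
        if inst.provenance != "original":
            raise ValidationError(
                f"instance {inst.instance_id!r} is already augmented"
            )
    seen: dict[tuple[tuple[str, str], str], float] = {
        (inst.pair, inst.cell_line): inst.synergy_score for inst in instances
    }
    generated: list[SynergyInstance] = []
    serial = 0
    for inst in instances:
        for position, replaced, partner in (
            ("a", inst.drug_a, inst.drug_b),
            ("b", inst.drug_b, inst.drug_a),
        ):
            for cand_id, _score in subs.for_drug(replaced):
                if cand_id == partner:
                    continue  # would collapse into a self-pair
                key = (canonical_pair(cand_id, partner), inst.cell_line)
                if key in seen:
                    if seen[key] != inst.synergy_score:
                        logger.info(
                            "duplicate %s with conflicting scores; keeping first", key
                        )
                    continue
                seen[key] = inst.synergy_score
                serial += 1
                generated.append(
                    SynergyInstance(
                        instance_id=f"A{serial:07d}",
                        drug_a=cand_id,
                        drug_b=partner,
                        cell_line=inst.cell_line,
                        synergy_score=inst.synergy_score,
                        qa_score=inst.qa_score,
                        provenance="augmented",
                        parent_id=inst.instance_id,
                        substituted_position=position,
                    )
                )
    return list(instances) + generated


@dataclass(frozen=True)
class LabelReport:
    """Class counts of a labeled dataset with derived totals."""

    n_synergistic: int
    n_antagonistic: int
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return self.n_synergistic + self.n_antagonistic

    @property
    def synergistic_prevalence(self) -> float:
        if self.total == 0:
            return float("nan")
        return self.n_synergistic / self.total


def label_instances(
    instances: Sequence[SynergyInstance],
    syn_cut: float = 20.0,
    ant_cut: float = -20.0,
) -> tuple[list[LabeledInstance], LabelReport]:
    """Threshold synergy scores into classes, dropping the ambiguous middle.

    score >= syn_cut -> synergistic; score <= ant_cut -> antagonistic;
    anything strictly in between is excluded.
    """
    if not syn_cut > ant_cut:
        raise ValidationError("syn_cut must exceed ant_cut")
    labeled: list[LabeledInstance] = []
    n_syn = n_ant = n_drop = 0
    for inst in instances:
        if inst.synergy_score >= syn_cut:
            label = SYNERGISTIC
            n_syn += 1
        elif inst.synergy_score <= ant_cut:
            label = ANTAGONISTIC
            n_ant += 1
        else:
            n_drop += 1
            continue
        labeled.append(
            LabeledInstance(label=label, **{f: getattr(inst, f) for f in _INSTANCE_FIELDS})
        )
    return labeled, LabelReport(
        n_synergistic=n_syn, n_antagonistic=n_ant, n_excluded=n_drop
    )


_INSTANCE_FIELDS = (
    "instance_id",
    "drug_a",
    "drug_b",
    "cell_line",
    "synergy_score",
    "qa_score",
    "provenance",
    "parent_id",
    "substituted_position",
)


@dataclass(frozen=True)
class AugmentationReport:
    """What ratio-preserving augmentation actually added."""

    added_synergistic: int
    added_antagonistic: int
    pool_synergistic: int
    pool_antagonistic: int

    @property
    def shortfall(self) -> dict[str, int]:
        return {
            SYNERGISTIC: self.pool_synergistic - self.added_synergistic,
            ANTAGONISTIC: self.pool_antagonistic - self.added_antagonistic,
        }


def ratio_preserving_augment(
    train: Sequence[LabeledInstance],
    pool: Sequence[LabeledInstance],
    seed: int = 0,
    max_total: Optional[int] = None,
) -> tuple[list[LabeledInstance], AugmentationReport]:
    """Add augmented instances while preserving the train class ratio.

    Every pool instance must be augmented and derive from a parent inside
    `train` (the leakage rule).  Additions alternate greedily between the
    classes so the running synergistic:antagonistic ratio of the added
    instances tracks the ratio of `train`; a one-sided pool is drawn down
    only as far as the ratio tolerates, and the report records the unused
    remainder.  Selection within a class is a seeded shuffle, so the
    result is deterministic for a given seed.
    """
    train_ids = {inst.instance_id for inst in train}
    for p in pool:
        if p.provenance != "augmented" or p.parent_id is None:
            raise ValidationError(
                f"pool instance {p.instance_id!r} is not an augmented instance"
            )
        if p.parent_id not in train_ids:
            raise ValidationError(
                f"pool instance {p.instance_id!r} references parent "
                f"{p.parent_id!r} outside the training set"
            )
    n_syn = sum(1 for i in train if i.label == SYNERGISTIC)
    n_ant = len(train) - n_syn
    pool_syn = [p for p in pool if p.label == SYNERGISTIC]
    pool_ant = [p for p in pool if p.label == ANTAGONISTIC]
    rng = np.random.default_rng(seed)
    rng.shuffle(pool_syn)
    rng.shuffle(pool_ant)

    if n_ant == 0 or n_syn == 0:
        # degenerate one-class training set: only same-class additions make sense
        picked = pool_syn if n_ant == 0 else pool_ant
        cap = len(picked) if max_total is None else min(len(picked), max_total)
        added = picked[:cap]
    else:
        ratio = n_syn / n_ant
        tol = max(ratio, 1.0 / ratio, 1.0)
        added = []
        err = 0.0  # a_syn - ratio * a_ant, in synergistic-instance units
        i_syn = i_ant = 0
        cap = (len(pool_syn) + len(pool_ant)) if max_total is None else max_total
        while len(added) < cap:
            can_syn = i_syn < len(pool_syn) and abs(err + 1.0) <= tol
            can_ant = i_ant < len(pool_ant) and abs(err - ratio) <= tol
            if can_syn and can_ant:
                # pick whichever keeps the running ratio closest; tie -> antagonistic
                if abs(err + 1.0) < abs(err - ratio):
                    can_ant = False
                else:
                    can_syn = False
            if can_syn:
                added.append(pool_syn[i_syn])
                i_syn += 1
                err += 1.0
            elif can_ant:
                added.append(pool_ant[i_ant])
                i_ant += 1
                err -= ratio
            else:
                break
    report = AugmentationReport(
        added_synergistic=sum(1 for p in added if p.label == SYNERGISTIC),
        added_antagonistic=sum(1 for p in added if p.label == ANTAGONISTIC),
        pool_synergistic=len(pool_syn),
        pool_antagonistic=len(pool_ant),
    )
    return list(train) + added, report


@dataclass(frozen=True)
class DistributionSummary:
    """Population mean/spread and fixed-width histogram of synergy scores."""

    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n: int


def synergy_distribution_summary(
    instances: Sequence[SynergyInstance], bin_width: float = 10.0
) -> DistributionSummary:
    """Summarize a synergy-score distribution (population sd, fixed-width bins)."""
    if not instances:
        raise ValidationError("cannot summarize an empty dataset")
    scores = np.array([i.synergy_score for i in instances], dtype=float)
    lo = bin_width * math.floor(scores.min() / bin_width)
    hi = bin_width * math.ceil(scores.max() / bin_width)
    if hi == lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(scores, bins=edges)
    return DistributionSummary(
        mean=float(scores.mean()),
        sd=float(scores.std(ddof=0)),
        bin_edges=edges,
        counts=counts.astype(np.int64),
        n=scores.size,
    )
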