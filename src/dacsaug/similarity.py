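"""Pairwise drug-similarity metrics and the combined DACS score.

Three complementary views of how alike two drugs are:

* pharmacological response — Kendall tau-b rank correlation between the
  two drugs' pIC50 potency profiles over the cancer cell lines both were
  tested on as monotherapies;
* molecular mechanism of action — Matthews correlation coefficient (MCC)
  over the 2x2 contingency of target proteins (targeted by both / only
  one / neither drug) within a fixed protein universe;
* chemical structure — Tanimoto coefficient (TC) between path-based
  binary molecular fingerprints.

TC and MCC combine into the drug action/chemical similarity score

    DACS = sqrt(TC**2 + max(MCC, 0)**2)

which ranges from 0 to sqrt(2); a negative MCC contributes nothing, since
anti-correlated target sets are treated as absence of mechanistic
similarity rather than evidence of dissimilar pharmacology.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .errors import ValidationError

__all__ = [
    "MonotherapyProfile",
    "ConcordanceCounts",
    "TargetContingency",
    "DrugRecord",
    "PairSimilarity",
    "concordance_counts",
    "kendall_tau_b",
    "target_contingency",
    "target_mcc",
    "tanimoto",
    "dacs",
    "pair_similarity",
    "pairwise_similarity_table",
    "bit_fingerprint",
]

DACS_MAX = math.sqrt(2.0)


def bit_fingerprint(on_bits: Iterable[int], length: int) -> np.ndarray:
    """Build a boolean fingerprint of `length` bits with `on_bits` set."""
    fp = np.zeros(length, dtype=bool)
    idx = np.fromiter(on_bits, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= length):
        raise ValidationError(f"fingerprint bit index out of range [0, {length})")
    fp[idx] = True
    return fp


@dataclass(frozen=True)
class MonotherapyProfile:
    """Per-drug map of cell line -> pIC50 from monotherapy screens.

    pIC50 is -log10 of the half-maximal inhibitory concentration (molar);
    larger values mean stronger growth inhibition.
    """

    drug_id: str
    responses: Mapping[str, float]

    def __post_init__(self) -> None:
        for cell, value in self.responses.items():
            if not math.isfinite(value):
                raise ValidationError(
                    f"non-finite pIC50 for drug {self.drug_id!r}, cell {cell!r}"
                )

    def common_cells(self, other: "MonotherapyProfile") -> list[str]:
        return sorted(set(self.responses) & set(other.responses))


@dataclass(frozen=True)
class ConcordanceCounts:
    """Explicit pair classification behind the tau-b statistic.

    Over the m cell lines shared by two drugs, each of the m(m-1)/2
    cell-line pairs is concordant, discordant, tied only in the first
    ranking, tied only in the second, or tied in both.
    """

    nc: int
    nd: int
    n1: int
    n2: int
    n_both_tied: int
    m: int

    @property
    def tau(self) -> float:
        denom = math.sqrt((self.nc + self.nd + self.n1) * (self.nc + self.nd + self.n2))
        if self.m < 2 or denom == 0.0:
            return 0.0
        return (self.nc - self.nd) / denom


def concordance_counts(x: Iterable[float], y: Iterable[float]) -> ConcordanceCounts:
    """Classify every (i, j) pair of observations (vectorized, exact counts)."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError("rank lists must have equal length")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValidationError("non-finite value in rank list")
    m = xa.size
    iu = np.triu_indices(m, k=1)
    sx = np.sign(xa[:, None] - xa[None, :])[iu]
    sy = np.sign(ya[:, None] - ya[None, :])[iu]
    nb = int(np.count_nonzero((sx == 0) & (sy == 0)))
    n1 = int(np.count_nonzero((sx == 0) & (sy != 0)))
    n2 = int(np.count_nonzero((sx != 0) & (sy == 0)))
    nc = int(np.count_nonzero(sx * sy > 0))
    nd = int(np.count_nonzero(sx * sy < 0))
    return ConcordanceCounts(nc=nc, nd=nd, n1=n1, n2=n2, n_both_tied=nb, m=m)


def kendall_tau_b(
    profile_a: MonotherapyProfile, profile_b: MonotherapyProfile
) -> float:
    """Kendall tau-b between two potency profiles on their shared cell lines.

    Returns exactly 0.0 when fewer than two cell lines are shared, or when
    either profile is constant over the intersection (tie-corrected
    denominator of zero): both situations carry no ordinal information.
    """
    common = profile_a.common_cells(profile_b)
    if len(common) < 2:
        return 0.0
    x = np.array([profile_a.responses[c] for c in common], dtype=float)
    y = np.array([profile_b.responses[c] for c in common], dtype=float)
    return concordance_counts(x, y).tau


@dataclass(frozen=True)
class TargetContingency:
    """2x2 protein-target contingency of two drugs within a universe."""

    t_both: int
    n_neither: int
    a_only_first: int
    b_only_second: int
    universe_size: int

    def __post_init__(self) -> None:
        total = self.t_both + self.n_neither + self.a_only_first + self.b_only_second
        if total != self.universe_size:
            raise ValidationError("contingency cells must sum to the universe size")
        if min(self.t_both, self.n_neither, self.a_only_first, self.b_only_second) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def mcc(self) -> float:
        t, n, a, b = self.t_both, self.n_neither, self.a_only_first, self.b_only_second
        denom = math.sqrt(float(t + a) * (t + b) * (n + a) * (n + b))
        if denom == 0.0:
            return 0.0
        return (t * n - a * b) / denom


def _check_subset(targets: frozenset, universe: frozenset, which: str) -> None:
    stray = targets - universe
    if stray:
        raise ValidationError(
            f"{which} targets outside the protein universe: {sorted(stray)[:5]}"
        )


def target_contingency(
    targets_a: Iterable[str], targets_b: Iterable[str], universe: Iterable[str]
) -> TargetContingency:
    ta, tb, uni = frozenset(targets_a), frozenset(targets_b), frozenset(universe)
    _check_subset(ta, uni, "first drug's")
    _check_subset(tb, uni, "second drug's")
    t = len(ta & tb)
    a = len(ta - tb)
    b = len(tb - ta)
    n = len(uni) - t - a - b
    return TargetContingency(
        t_both=t, n_neither=n, a_only_first=a, b_only_second=b, universe_size=len(uni)
    )


def target_mcc(
    targets_a: Iterable[str], targets_b: Iterable[str], universe: Iterable[str]
) -> float:
    """Matthews correlation between two drugs' target sets.

    A zero marginal (a drug targeting nothing, or everything, in the
    universe) makes the ratio undefined; 0.0 is returned as the neutral
    no-evidence value.
    """
    return target_contingency(targets_a, targets_b, universe).mcc


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient |a & b| / |a | b| between binary fingerprints.

    Two all-zero fingerprints give 0.0 (no shared chemistry evidence).
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("fingerprints must be 1-D and of equal length")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def dacs(tc: float, mcc: float) -> float:
    """Combine chemical (TC) and mechanistic (MCC) similarity.

    DACS = sqrt(tc^2 + max(mcc, 0)^2); negative MCC is clamped to zero.
    """
    eps = 1e-9
    if not (-eps <= tc <= 1.0 + eps):
        raise ValidationError(f"tc out of range [0, 1]: {tc}")
    if not (-1.0 - eps <= mcc <= 1.0 + eps):
        raise ValidationError(f"mcc out of range [-1, 1]: {mcc}")
    return math.hypot(min(max(tc, 0.0), 1.0), max(mcc, 0.0))


@dataclass(frozen=True)
class DrugRecord:
    """A drug: identifier, optional SMILES, fingerprint, target-protein set."""

    drug_id: str
    fingerprint: np.ndarray
    targets: frozenset = frozenset()
    smiles: Optional[str] = None

    def __post_init__(self) -> None:
        fp = np.asarray(self.fingerprint, dtype=bool)
        if fp.ndim != 1:
            raise ValidationError(f"fingerprint of {self.drug_id!r} must be 1-D")
        object.__setattr__(self, "fingerprint", fp)
        object.__setattr__(self, "targets", frozenset(self.targets))


@dataclass(frozen=True)
class PairSimilarity:
    """All similarity metrics for one unordered drug pair.

    The pair is stored in canonical (lexicographic) order; every metric is
    symmetric so the orientation is presentation only.
    """

    drug_a: str
    drug_b: str
    tc: float
    mcc: float
    tau: float
    dacs: float
    n_common_cells: int

    def __post_init__(self) -> None:
        if self.drug_a > self.drug_b:
            raise ValidationError("pair must be in canonical lexicographic order")


def pair_similarity(
    rec_a: DrugRecord,
    rec_b: DrugRecord,
    profiles: Mapping[str, MonotherapyProfile],
    universe: Iterable[str],
) -> PairSimilarity:
    """Compute TC, MCC, tau-b and DACS for one drug pair."""
    if rec_a.drug_id > rec_b.drug_id:
        rec_a, rec_b = rec_b, rec_a
    tc = tanimoto(rec_a.fingerprint, rec_b.fingerprint)
    mcc = target_mcc(rec_a.targets, rec_b.targets, universe)
    pa = profiles.get(rec_a.drug_id)
    pb = profiles.get(rec_b.drug_id)
    if pa is None or pb is None:
        tau, n_common = 0.0, 0
    else:
        n_common = len(pa.common_cells(pb))
        tau = kendall_tau_b(pa, pb)
    return PairSimilarity(
        drug_a=rec_a.drug_id,
        drug_b=rec_b.drug_id,
        tc=tc,
        mcc=mcc,
        tau=tau,
        dacs=dacs(tc, mcc),
        n_common_cells=n_common,
    )


def pairwise_similarity_table(
    library: list[DrugRecord],
    profiles: Mapping[str, MonotherapyProfile],
    universe: Iterable[str],
) -> list[PairSimilarity]:
    """All-vs-all similarity over a drug library: n(n-1)/2 canonical pairs."""
    ids = [r.drug_id for r in library]
    if len(set(ids)) != len(ids):
        dupes = sorted({d for d in ids if ids.count(d) > 1})
        raise ValidationError(f"duplicate drug_ids in library: {dupes[:5]}")
    lengths = {r.fingerprint.size for r in library}
    if len(lengths) > 1:
        raise ValidationError(f"fingerprint lengths differ across library: {lengths}")
    uni = frozenset(universe)
    ordered = sorted(library, key=lambda r: r.drug_id)
    return [
        pair_similarity(a, b, profiles, uni)
        for a, b in itertools.combinations(ordered, 2)
    ]
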