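"""Self-contained synthetic cohorts with the structure the method assumes.

The generator emulates the shape of the real inputs — a synergy screen,
monotherapy potency profiles, drug-target associations, fingerprints,
gene expression, and tissue metadata — with an explicit latent cluster
structure: drugs in the same cluster share fingerprint bits and target
proteins and respond to cell lines along a shared potency profile, so
within-cluster pairs have high TC, high MCC, and positive Kendall tau.
Candidate (substitute) compounds belong to the same clusters but with a
per-candidate strength drawn from a range, giving the continuum of
similarity a real compound database shows.  The synergy score of a pair
is a latent surface over (cluster_a, cluster_b, tissue) plus Gaussian
noise, and augmented instances inherit their parent's score, so ground
truth is available for every assertion a test wants to make.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .similarity import DrugRecord, MonotherapyProfile, bit_fingerprint

__all__ = ["TISSUE_GROUPS", "CohortSpec", "Cohort", "generate_cohort", "worked_fixture"]

TISSUE_GROUPS = ("breast", "digestive", "excretory", "respiratory", "other")


@dataclass(frozen=True)
class CohortSpec:
    """Knobs of the synthetic cohort generator.

    Overlaps are fractions in [0, 1]: the share of a cluster's fingerprint
    bits / target proteins an in-cluster drug inherits (the remainder is
    private and random).  Candidates draw an additional per-candidate
    strength factor from `candidate_strength_range`, scaling both
    overlaps, so substitute quality spans a continuum.  pIC50 noise is in
    pIC50 units (dimensionless -log10 molar); synergy parameters are on
    the synergy-score scale, where +/-20 are the class boundaries.
    """

    n_clusters: int = 12
    drugs_per_cluster: int = 4
    n_candidate_drugs: int = 40
    n_cell_lines: int = 25
    tissues: tuple[str, ...] = TISSUE_GROUPS
    n_genes: int = 200
    fingerprint_length: int = 1024
    n_universe: int = 400
    bits_per_drug: int = 96
    targets_per_drug: int = 12
    within_cluster_bit_overlap: float = 0.9
    target_overlap: float = 0.9
    candidate_strength_range: tuple[float, float] = (0.55, 1.0)
    response_noise_sd: float = 0.3
    synergy_mean: float = 10.0
    synergy_effect_size: float = 25.0
    synergy_tissue_sd: float = 20.0
    synergy_noise_sd: float = 15.0
    n_instances: int = 900
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_clusters,
            self.drugs_per_cluster,
            self.n_candidate_drugs,
            self.n_cell_lines,
            self.n_genes,
            self.fingerprint_length,
            self.n_universe,
            self.bits_per_drug,
            self.targets_per_drug,
            self.n_instances,
        )
        if min(counts) <= 0:
            raise ValidationError("all cohort counts must be positive")
        for name in ("within_cluster_bit_overlap", "target_overlap"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        lo, hi = self.candidate_strength_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("candidate_strength_range must be within [0, 1]")
        if self.bits_per_drug > self.fingerprint_length:
            raise ValidationError("bits_per_drug exceeds the fingerprint length")
        if self.targets_per_drug > self.n_universe:
            raise ValidationError("targets_per_drug exceeds the protein universe")
        if len(self.tissues) == 0:
            raise ValidationError("at least one tissue group is required")


@dataclass(frozen=True)
class Cohort:
    """A generated cohort plus the latent ground truth behind it.

    `drug_cluster` covers originals and candidates; `latent_synergy`
    reconstructs the noiseless synergy surface for any pair of drugs on
    any cell line — for test assertions only, never consumed by the
    method itself.
    """

    spec: CohortSpec
    originals: tuple[DrugRecord, ...]
    candidates: tuple[DrugRecord, ...]
    drug_cluster: Mapping[str, int]
    profiles: Mapping[str, MonotherapyProfile]
    universe: frozenset
    cells: tuple[str, ...]
    cell_tissue: Mapping[str, str]
    expression: pd.DataFrame
    instances: tuple
    latent_pair_effect: Mapping[tuple[int, int], float]
    latent_tissue_effect: Mapping[tuple[int, int, str], float]

    @property
    def drug_records(self) -> dict[str, DrugRecord]:
        return {r.drug_id: r for r in (*self.originals, *self.candidates)}

    def latent_synergy(self, drug_a: str, drug_b: str, cell: str) -> float:
        ca, cb = sorted((self.drug_cluster[drug_a], self.drug_cluster[drug_b]))
        tissue = self.cell_tissue[cell]
        return (
            self.latent_pair_effect[(ca, cb)]
            + self.latent_tissue_effect[(ca, cb, tissue)]
        )


def _mixed_bits(
    rng: np.random.Generator,
    cluster_pool: np.ndarray,
    overlap: float,
    n_bits: int,
    space: int,
) -> np.ndarray:
    """Inherit round(overlap * n_bits) cluster positions, fill up privately."""
    n_keep = int(round(overlap * n_bits))
    kept = rng.choice(cluster_pool, size=n_keep, replace=False)
    outside = np.setdiff1d(np.arange(space), cluster_pool, assume_unique=False)
    private = rng.choice(outside, size=n_bits - n_keep, replace=False)
    return np.concatenate([kept, private])


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a fully reproducible cohort from a spec seed.

    All randomness flows from `spec.seed` through named child streams, so
    each table is individually reproducible regardless of how the others
    are consumed.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_fp, rng_tg, rng_resp, rng_cell, rng_syn, rng_inst = (
        np.random.default_rng(s) for s in streams
    )

    universe = frozenset(f"P{i:04d}" for i in range(spec.n_universe))
    universe_idx = np.array(sorted(universe))

    # latent cluster scaffolding
    cluster_bits = [
        rng_fp.choice(spec.fingerprint_length, size=spec.bits_per_drug, replace=False)
        for _ in range(spec.n_clusters)
    ]
    cluster_targets = [
        rng_tg.choice(spec.n_universe, size=spec.targets_per_drug, replace=False)
        for _ in range(spec.n_clusters)
    ]

    # cell lines spread round-robin across the tissue groups
    cells = tuple(f"CL{i:03d}" for i in range(spec.n_cell_lines))
    cell_tissue = {
        cell: spec.tissues[i % len(spec.tissues)] for i, cell in enumerate(cells)
    }
    cluster_response = rng_resp.normal(6.0, 1.0, size=(spec.n_clusters, spec.n_cell_lines))

    def _make_drug(drug_id: str, cluster: int, strength: float) -> DrugRecord:
        bits = _mixed_bits(
            rng_fp,
            cluster_bits[cluster],
            strength * spec.within_cluster_bit_overlap,
            spec.bits_per_drug,
            spec.fingerprint_length,
        )
        targets = _mixed_bits(
            rng_tg,
            cluster_targets[cluster],
            strength * spec.target_overlap,
            spec.targets_per_drug,
            spec.n_universe,
        )
        return DrugRecord(
            drug_id=drug_id,
            fingerprint=bit_fingerprint(bits, spec.fingerprint_length),
            targets=frozenset(universe_idx[targets]),
        )

    originals: list[DrugRecord] = []
    drug_cluster: dict[str, int] = {}
    for c in range(spec.n_clusters):
        for j in range(spec.drugs_per_cluster):
            drug_id = f"D{c * spec.drugs_per_cluster + j + 1:03d}"
            originals.append(_make_drug(drug_id, c, strength=1.0))
            drug_cluster[drug_id] = c

    candidates: list[DrugRecord] = []
    lo, hi = spec.candidate_strength_range
    for i in range(spec.n_candidate_drugs):
        cluster = int(rng_fp.integers(spec.n_clusters))
        strength = float(rng_fp.uniform(lo, hi))
        drug_id = f"S{i + 1:03d}"
        candidates.append(_make_drug(drug_id, cluster, strength))
        drug_cluster[drug_id] = cluster

    profiles = {
        rec.drug_id: MonotherapyProfile(
            drug_id=rec.drug_id,
            responses={
                cell: float(
                    cluster_response[drug_cluster[rec.drug_id], i]
                    + rng_resp.normal(0.0, spec.response_noise_sd)
                )
                for i, cell in enumerate(cells)
            },
        )
        for rec in (*originals, *candidates)
    }

    # tissue-structured expression: tissue mean + per-cell noise
    tissue_mean = {
        t: rng_cell.normal(0.0, 1.0, size=spec.n_genes) for t in spec.tissues
    }
    expression = pd.DataFrame(
        {
            cell: tissue_mean[cell_tissue[cell]]
            + rng_cell.normal(0.0, 0.5, size=spec.n_genes)
            for cell in cells
        },
        index=[f"G{i:04d}" for i in range(spec.n_genes)],
    )

    # latent synergy surface over unordered cluster pairs and tissues
    latent_pair: dict[tuple[int, int], float] = {}
    latent_tissue: dict[tuple[int, int, str], float] = {}
    for ca, cb in itertools.combinations_with_replacement(range(spec.n_clusters), 2):
        latent_pair[(ca, cb)] = float(
            rng_syn.normal(spec.synergy_mean, spec.synergy_effect_size)
        )
        for t in spec.tissues:
            latent_tissue[(ca, cb, t)] = float(
                rng_syn.normal(0.0, spec.synergy_tissue_sd)
            )

    # sample distinct (pair, cell) combinations among the original drugs
    from .augmentation import SynergyInstance  # local import avoids a cycle

    ids = [r.drug_id for r in originals]
    all_pairs = list(itertools.combinations(range(len(ids)), 2))
    combos = [(p, c) for p in range(len(all_pairs)) for c in range(len(cells))]
    take = min(spec.n_instances, len(combos))
    chosen = rng_inst.choice(len(combos), size=take, replace=False)
    instances = []
    for serial, flat in enumerate(sorted(chosen.tolist())):
        pair_idx, cell_idx = combos[flat]
        i, j = all_pairs[pair_idx]
        cell = cells[cell_idx]
        ca, cb = sorted((drug_cluster[ids[i]], drug_cluster[ids[j]]))
        score = (
            latent_pair[(ca, cb)]
            + latent_tissue[(ca, cb, cell_tissue[cell])]
            + rng_inst.normal(0.0, spec.synergy_noise_sd)
        )
        instances.append(
            SynergyInstance(
                instance_id=f"O{serial + 1:05d}",
                drug_a=ids[i],
                drug_b=ids[j],
                cell_line=cell,
                synergy_score=float(score),
            )
        )

    return Cohort(
        spec=spec,
        originals=tuple(originals),
        candidates=tuple(candidates),
        drug_cluster=drug_cluster,
        profiles=profiles,
        universe=universe,
        cells=cells,
        cell_tissue=cell_tissue,
        expression=expression,
        instances=tuple(instances),
        latent_pair_effect=latent_pair,
        latent_tissue_effect=latent_tissue,
    )


def worked_fixture() -> Cohort:
    """A fixed micro-cohort small enough to verify entirely by hand.

    Four original drugs in two chemical families, two candidate
    substitutes, three cell lines in three tissue groups, and four
    synergy instances.  Everything is written out literally — no random
    number generator is involved — so regeneration is byte-identical and
    every similarity value can be enumerated on paper.
    """
    length = 16
    fps = {
        "d1": (0, 1, 2, 3, 4, 5, 6, 7),
        "d2": (0, 1, 2, 3, 4, 5, 8, 9),
        "d3": (8, 9, 10, 11, 12, 13, 14, 15),
        "d4": (0, 1, 2, 3, 10, 11, 12, 13),
        "s1": (0, 1, 2, 3, 4, 5, 6, 8),
        "s2": (8, 9, 10, 11, 12, 13, 14, 7),
    }
    targets = {
        "d1": ("p1", "p2", "p3"),
        "d2": ("p1", "p2", "p4"),
        "d3": ("p5", "p6"),
        "d4": ("p1", "p5"),
        "s1": ("p1", "p2", "p3"),
        "s2": ("p5", "p6", "p7"),
    }
    clusters = {"d1": 0, "d2": 0, "d3": 1, "d4": 1, "s1": 0, "s2": 1}
    universe = frozenset(f"p{i}" for i in range(1, 9))

    def record(drug_id: str) -> DrugRecord:
        return DrugRecord(
            drug_id=drug_id,
            fingerprint=bit_fingerprint(fps[drug_id], length),
            targets=frozenset(targets[drug_id]),
        )

    responses = {
        "d1": {"c1": 7.0, "c2": 6.0, "c3": 5.0},
        "d2": {"c1": 7.5, "c2": 6.5, "c3": 5.5},
        "d3": {"c1": 5.0, "c2": 6.0, "c3": 7.0},
        "d4": {"c1": 6.0, "c2": 6.0},
        "s1": {"c1": 6.8, "c2": 5.9, "c3": 5.1},
        "s2": {"c1": 5.2, "c2": 6.1, "c3": 6.9},
    }
    profiles = {
        d: MonotherapyProfile(drug_id=d, responses=r) for d, r in responses.items()
    }
    cells = ("c1", "c2", "c3")
    cell_tissue = {"c1": "breast", "c2": "digestive", "c3": "other"}
    expression = pd.DataFrame(
        {
            "c1": [1.0, 0.0, 0.5, -1.0, 2.0],
            "c2": [0.0, 1.0, -0.5, 1.0, 0.0],
            "c3": [-1.0, 0.5, 1.5, 0.0, -2.0],
        },
        index=[f"g{i}" for i in range(1, 6)],
    )

    from .augmentation import SynergyInstance

    instances = (
        SynergyInstance(
            instance_id="O00001", drug_a="d1", drug_b="d2",
            cell_line="c1", synergy_score=30.0, qa_score=1.0,
        ),
        SynergyInstance(
            instance_id="O00002", drug_a="d1", drug_b="d3",
            cell_line="c2", synergy_score=-25.0,
        ),
        SynergyInstance(
            instance_id="O00003", drug_a="d2", drug_b="d4",
            cell_line="c3", synergy_score=5.0,
        ),
        SynergyInstance(
            instance_id="O00004", drug_a="d3", drug_b="d4",
            cell_line="c1", synergy_score=22.0,
        ),
    )
    spec = CohortSpec(
        n_clusters=2,
        drugs_per_cluster=2,
        n_candidate_drugs=2,
        n_cell_lines=3,
        tissues=("breast", "digestive", "other"),
        n_genes=5,
        fingerprint_length=length,
        n_universe=8,
        bits_per_drug=8,
        targets_per_drug=3,
        n_instances=4,
        seed=0,
    )
    return Cohort(
        spec=spec,
        originals=tuple(record(d) for d in ("d1", "d2", "d3", "d4")),
        candidates=tuple(record(d) for d in ("s1", "s2")),
        drug_cluster=clusters,
        profiles=profiles,
        universe=universe,
        cells=cells,
        cell_tissue=cell_tissue,
        expression=expression,
        instances=instances,
        latent_pair_effect={(0, 0): 30.0, (0, 1): -10.0, (1, 1): 22.0},
        latent_tissue_effect={
            (ca, cb, t): 0.0
            for ca, cb in ((0, 0), (0, 1), (1, 1))
            for t in ("breast", "digestive", "other")
        },
    )
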