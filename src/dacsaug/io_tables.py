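"""Readers and writers for the pipeline's tabular formats.

Canonical dialect: tab-separated, header row, UTF-8, '.' decimal;
comma-separated files are accepted on read (by .csv extension).  Lines
starting with '#' are provenance headers and are ignored on read.
Identifiers are opaque strings — no case folding, no normalization.

Tables:

* synergy           DRUG_A  DRUG_B  CELL_LINE  SYNERGY_SCORE  [QA]
                    (+ INSTANCE_ID PROVENANCE PARENT_ID SUBSTITUTED_POSITION
                     on augmented output, + LABEL on labeled output)
* monotherapy       DRUG  CELL_LINE  PIC50
* drug-target       DRUG  PROTEIN  [SCORE]
* structures        DRUG  SMILES and/or FINGERPRINT (packed-bit hex)
* expression        GENE  <one column per cell line>
* cell metadata     CELL_LINE  TISSUE
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .augmentation import LabeledInstance, SynergyInstance
from .chem import (
    DEFAULT_FP_BITS,
    fingerprint_from_hex,
    fingerprint_from_smiles,
    fingerprint_to_hex,
)
from .errors import ValidationError
from .similarity import DrugRecord, MonotherapyProfile, PairSimilarity
from .threshold import CutoffResult, ThresholdCurve

FLOAT_FORMAT = "%.6f"  # fixed output precision so reruns diff clean


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_frame(path: Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    except FileNotFoundError:
        raise ValidationError(f"{path}: file not found") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return df

def _numeric(df: pd.DataFrame, column: str, path: Path) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValidationError(
            f"{path}: malformed number in column {column!r} at line {line}"
        )
    return values.to_numpy(dtype=float)


def provenance_header(seed: Optional[int] = None, config: Optional[Mapping] = None) -> str:
    parts = [f"# dacsaug {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        parts.append(f"config={digest}")
    return " ".join(parts) + "\n"


def _write_frame(
    df: pd.DataFrame,
    path: Path,
    seed: Optional[int] = None,
    config: Optional[Mapping] = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(provenance_header(seed, config))
        df.to_csv(handle, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# synergy instances


def read_synergy_table(path: Path) -> list[SynergyInstance]:
    df = _read_frame(path, ["DRUG_A", "DRUG_B", "CELL_LINE", "SYNERGY_SCORE"])
    scores = _numeric(df, "SYNERGY_SCORE", path)
    qa = _numeric(df, "QA", path) if "QA" in df.columns else None
    instances = []
    for i, row in enumerate(df.itertuples(index=False)):
        instances.append(
            SynergyInstance(
                instance_id=(
                    row.INSTANCE_ID if "INSTANCE_ID" in df.columns else f"O{i + 1:05d}"
                ),
                drug_a=row.DRUG_A,
                drug_b=row.DRUG_B,
                cell_line=row.CELL_LINE,
                synergy_score=float(scores[i]),
                qa_score=(
                    None if qa is None or np.isnan(qa[i]) else float(qa[i])
                ),
                provenance=(
                    row.PROVENANCE if "PROVENANCE" in df.columns else "original"
                ),
                parent_id=(
                    row.PARENT_ID
                    if "PARENT_ID" in df.columns and pd.notna(row.PARENT_ID)
                    else None
                ),
                substituted_position=(
                    row.SUBSTITUTED_POSITION
                    if "SUBSTITUTED_POSITION" in df.columns
                    else "none"
                ),
            )
        )
    return instances


def synergy_frame(instances: Sequence[SynergyInstance]) -> pd.DataFrame:
    rows = []
    for inst in instances:
        row = {
            "INSTANCE_ID": inst.instance_id,
            "DRUG_A": inst.drug_a,
            "DRUG_B": inst.drug_b,
            "CELL_LINE": inst.cell_line,
            "SYNERGY_SCORE": inst.synergy_score,
            "QA": inst.qa_score,
            "PROVENANCE": inst.provenance,
            "PARENT_ID": inst.parent_id,
            "SUBSTITUTED_POSITION": inst.substituted_position,
        }
        if isinstance(inst, LabeledInstance):
            row["LABEL"] = inst.label
        rows.append(row)
    return pd.DataFrame(rows)


def write_synergy_table(
    instances: Sequence[SynergyInstance], path: Path, seed: Optional[int] = None
) -> None:
    _write_frame(synergy_frame(instances), path, seed=seed)


def read_labeled_table(path: Path) -> list[LabeledInstance]:
    df = _read_frame(path, ["DRUG_A", "DRUG_B", "CELL_LINE", "SYNERGY_SCORE", "LABEL"])
    base = read_synergy_table(path)
    return [
        LabeledInstance(
            label=df["LABEL"].iloc[i],
            **{f: getattr(inst, f) for f in (
                "instance_id", "drug_a", "drug_b", "cell_line", "synergy_score",
                "qa_score", "provenance", "parent_id", "substituted_position",
            )},
        )
        for i, inst in enumerate(base)
    ]


# ---------------------------------------------------------------------------
# monotherapy profiles


def read_monotherapy(path: Path) -> dict[str, MonotherapyProfile]:
    df = _read_frame(path, ["DRUG", "CELL_LINE", "PIC50"])
    values = _numeric(df, "PIC50", path)
    dup = df.duplicated(subset=["DRUG", "CELL_LINE"], keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:10]]
        raise ValidationError(
            f"{path}: duplicate (DRUG, CELL_LINE) rows at lines {lines}"
        )
    responses: dict[str, dict[str, float]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        responses.setdefault(row.DRUG, {})[row.CELL_LINE] = float(values[i])
    return {
        drug: MonotherapyProfile(drug_id=drug, responses=r)
        for drug, r in responses.items()
    }


def write_monotherapy(
    profiles: Mapping[str, MonotherapyProfile], path: Path, seed: Optional[int] = None
) -> None:
    rows = [
        {"DRUG": drug, "CELL_LINE": cell, "PIC50": value}
        for drug in sorted(profiles)
        for cell, value in sorted(profiles[drug].responses.items())
    ]
    _write_frame(pd.DataFrame(rows), path, seed=seed)


# ---------------------------------------------------------------------------
# drug-target associations


def read_targets(
    path: Path, min_score: Optional[float] = None
) -> dict[str, frozenset]:
    """STITCH-style association table; optional confidence filter."""
    df = _read_frame(path, ["DRUG", "PROTEIN"])
    if min_score is not None:
        if "SCORE" not in df.columns:
            raise ValidationError(f"{path}: confidence filter needs a SCORE column")
        df = df[_numeric(df, "SCORE", path) >= min_score]
    out: dict[str, set] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.DRUG, set()).add(row.PROTEIN)
    return {drug: frozenset(proteins) for drug, proteins in out.items()}


def write_targets(
    targets: Mapping[str, Iterable[str]], path: Path, seed: Optional[int] = None
) -> None:
    rows = [
        {"DRUG": drug, "PROTEIN": protein}
        for drug in sorted(targets)
        for protein in sorted(targets[drug])
    ]
    _write_frame(pd.DataFrame(rows), path, seed=seed)


# ---------------------------------------------------------------------------
# structures / fingerprints


def read_structures(
    path: Path, n_bits: int = DEFAULT_FP_BITS
) -> dict[str, DrugRecord]:
    """Read drug structures: SMILES (fingerprinted on load) or hex fingerprints."""
    df = _read_frame(path, ["DRUG"])
    has_smiles = "SMILES" in df.columns
    has_fp = "FINGERPRINT" in df.columns
    if not (has_smiles or has_fp):
        raise ValidationError(f"{path}: need a SMILES or FINGERPRINT column")
    dup = df.duplicated(subset=["DRUG"], keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:10]]
        raise ValidationError(f"{path}: duplicate DRUG rows at lines {lines}")
    records: dict[str, DrugRecord] = {}
    for row in df.itertuples(index=False):
        smiles = getattr(row, "SMILES", None) if has_smiles else None
        if has_fp and pd.notna(getattr(row, "FINGERPRINT", None)):
            fp = fingerprint_from_hex(row.FINGERPRINT, n_bits)
        elif smiles and pd.notna(smiles):
            fp = fingerprint_from_smiles(smiles, n_bits)
        else:
            raise ValidationError(f"{path}: drug {row.DRUG!r} has no structure")
        records[row.DRUG] = DrugRecord(
            drug_id=row.DRUG,
            fingerprint=fp,
            smiles=smiles if smiles and pd.notna(smiles) else None,
        )
    return records


def write_structures(
    records: Mapping[str, DrugRecord], path: Path, seed: Optional[int] = None
) -> None:
    rows = [
        {
            "DRUG": drug,
            "SMILES": records[drug].smiles,
            "FINGERPRINT": fingerprint_to_hex(records[drug].fingerprint),
        }
        for drug in sorted(records)
    ]
    _write_frame(pd.DataFrame(rows), path, seed=seed)


# ---------------------------------------------------------------------------
# expression and cell metadata


def read_expression(path: Path) -> pd.DataFrame:
    df = _read_frame(path, ["GENE"])
    df = df.set_index("GENE")
    return df.apply(pd.to_numeric, errors="raise")


def write_expression(
    expression: pd.DataFrame, path: Path, seed: Optional[int] = None
) -> None:
    _write_frame(expression.rename_axis("GENE").reset_index(), path, seed=seed)


def read_cell_meta(path: Path) -> dict[str, str]:
    df = _read_frame(path, ["CELL_LINE", "TISSUE"])
    dup = df.duplicated(subset=["CELL_LINE"], keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:10]]
        raise ValidationError(f"{path}: duplicate CELL_LINE rows at lines {lines}")
    return dict(zip(df["CELL_LINE"], df["TISSUE"]))


def write_cell_meta(
    cell_tissue: Mapping[str, str], path: Path, seed: Optional[int] = None
) -> None:
    rows = [{"CELL_LINE": c, "TISSUE": t} for c, t in sorted(cell_tissue.items())]
    _write_frame(pd.DataFrame(rows), path, seed=seed)


# ---------------------------------------------------------------------------
# similarity tables and curves


def write_similarity_table(
    pairs: Sequence[PairSimilarity], path: Path, seed: Optional[int] = None
) -> None:
    rows = [
        {
            "DRUG_A": p.drug_a,
            "DRUG_B": p.drug_b,
            "TC": p.tc,
            "MCC": p.mcc,
            "TAU": p.tau,
            "N_COMMON_CELLS": p.n_common_cells,
            "DACS": p.dacs,
        }
        for p in pairs
    ]
    _write_frame(pd.DataFrame(rows), path, seed=seed)


def read_similarity_table(path: Path) -> list[PairSimilarity]:
    df = _read_frame(path, ["DRUG_A", "DRUG_B", "TC", "MCC", "TAU", "DACS"])
    tc = _numeric(df, "TC", path)
    mcc = _numeric(df, "MCC", path)
    tau = _numeric(df, "TAU", path)
    dacs_col = _numeric(df, "DACS", path)
    ncc = (
        _numeric(df, "N_COMMON_CELLS", path)
        if "N_COMMON_CELLS" in df.columns
        else np.zeros(len(df))
    )
    return [
        PairSimilarity(
            drug_a=row.DRUG_A,
            drug_b=row.DRUG_B,
            tc=float(tc[i]),
            mcc=float(mcc[i]),
            tau=float(tau[i]),
            dacs=float(dacs_col[i]),
            n_common_cells=int(ncc[i]),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def write_curve(curve: ThresholdCurve, path: Path, seed: Optional[int] = None) -> None:
    _write_frame(
        pd.DataFrame(
            {
                "THRESHOLD": curve.thresholds,
                "FRACTION_POSITIVE": curve.fraction_positive,
                "N_PAIRS": curve.n_pairs,
            }
        ),
        path,
        seed=seed,
    )


def read_curve(path: Path) -> ThresholdCurve:
    df = _read_frame(path, ["THRESHOLD", "FRACTION_POSITIVE", "N_PAIRS"])
    return ThresholdCurve(
        thresholds=_numeric(df, "THRESHOLD", path),
        fraction_positive=_numeric(df, "FRACTION_POSITIVE", path),
        n_pairs=_numeric(df, "N_PAIRS", path).astype(np.int64),
    )


def write_cutoff_report(
    result: CutoffResult, path: Path, seed: Optional[int] = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "version": __version__,
        "seed": seed,
        "found": result.found,
        "dacs_cutoff": None if not result.found else round(result.dacs_cutoff, 6),
        "fraction_positive_at_cutoff": (
            None if not result.found else round(result.fraction_positive_at_cutoff, 6)
        ),
        "n_substitutes_at_cutoff": (
            None if not result.found else round(result.n_substitutes_at_cutoff, 6)
        ),
    }
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# whole-cohort convenience


def write_cohort(cohort, out_dir: Path, seed: Optional[int] = None) -> dict[str, Path]:
    """Write the six input tables (plus latent cluster labels) for a cohort."""
    out = Path(out_dir)
    paths = {
        "synergy": out / "synergy.tsv",
        "monotherapy": out / "monotherapy.tsv",
        "targets": out / "targets.tsv",
        "structures": out / "structures.tsv",
        "expression": out / "expression.tsv",
        "cell_meta": out / "cell_meta.tsv",
        "clusters": out / "clusters.tsv",
    }
    write_synergy_table(cohort.instances, paths["synergy"], seed=seed)
    write_monotherapy(cohort.profiles, paths["monotherapy"], seed=seed)
    write_targets(
        {r.drug_id: r.targets for r in (*cohort.originals, *cohort.candidates)},
        paths["targets"],
        seed=seed,
    )
    write_structures(cohort.drug_records, paths["structures"], seed=seed)
    write_expression(cohort.expression, paths["expression"], seed=seed)
    write_cell_meta(cohort.cell_tissue, paths["cell_meta"], seed=seed)
    _write_frame(
        pd.DataFrame(
            [{"DRUG": d, "CLUSTER": c} for d, c in sorted(cohort.drug_cluster.items())]
        ),
        paths["clusters"],
        seed=seed,
    )
    return paths


@dataclass
class Datasets:
    """Validated in-memory view of the six input tables."""

    instances: list[SynergyInstance]
    profiles: dict[str, MonotherapyProfile]
    targets: dict[str, frozenset]
    structures: dict[str, DrugRecord]
    expression: pd.DataFrame
    cell_tissue: dict[str, str]

    @property
    def drug_records(self) -> dict[str, DrugRecord]:
        """Structures joined with target sets."""
        return {
            drug: DrugRecord(
                drug_id=drug,
                fingerprint=rec.fingerprint,
                targets=self.targets.get(drug, frozenset()),
                smiles=rec.smiles,
            )
            for drug, rec in self.structures.items()
        }

    @property
    def universe(self) -> frozenset:
        return frozenset().union(*self.targets.values()) if self.targets else frozenset()


def read_tables(
    synergy: Path,
    monotherapy: Path,
    targets: Path,
    structures: Path,
    expression: Path,
    cell_meta: Path,
    min_target_score: Optional[float] = None,
    n_bits: int = DEFAULT_FP_BITS,
) -> Datasets:
    """Read and cross-validate the six input tables.

    Referential integrity: every synergy instance must reference known
    drugs (structures table) and a cell line present in both the
    expression matrix and the metadata table.
    """
    data = Datasets(
        instances=read_synergy_table(synergy),
        profiles=read_monotherapy(monotherapy),
        targets=read_targets(targets, min_score=min_target_score),
        structures=read_structures(structures, n_bits=n_bits),
        expression=read_expression(expression),
        cell_tissue=read_cell_meta(cell_meta),
    )
    known_cells = set(data.expression.columns) & set(data.cell_tissue)
    for inst in data.instances:
        for drug in (inst.drug_a, inst.drug_b):
            if drug not in data.structures:
                raise ValidationError(
                    f"instance {inst.instance_id!r} references unknown drug {drug!r}"
                )
        if inst.cell_line not in known_cells:
            raise ValidationError(
                f"instance {inst.instance_id!r} references unknown cell "
                f"{inst.cell_line!r}"
            )
    return data
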