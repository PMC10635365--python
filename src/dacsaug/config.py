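"""Run configuration: one file describing a whole pipeline run.

A JSON or YAML file with the six input table paths and the knobs of the
augmentation/evaluation stages drives `run_pipeline`, which executes
similarity -> curves -> cutoff -> augment -> label -> split -> evaluate
and writes every intermediate table into the output directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

from .errors import ValidationError

__all__ = ["RunConfig", "load_config", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters for one end-to-end run."""

    synergy: Path
    monotherapy: Path
    targets: Path
    structures: Path
    expression: Path
    cell_meta: Path
    out_dir: Path
    dacs_cutoff: Union[float, str] = "auto"  # "auto" -> curve crossing
    syn_cut: float = 20.0
    ant_cut: float = -20.0
    cv_scheme: str = "tissue"  # or "random_stratified"
    classifiers: tuple[str, ...] = ("RF", "GBT")
    classifier_overrides: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0
    min_target_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cv_scheme not in ("tissue", "random_stratified"):
            raise ValidationError(f"unknown cv_scheme {self.cv_scheme!r}")
        if isinstance(self.dacs_cutoff, str) and self.dacs_cutoff != "auto":
            raise ValidationError("dacs_cutoff must be a number or 'auto'")
        for name in self.classifiers:
            if name not in ("RF", "GBT"):
                raise ValidationError(f"unknown classifier {name!r}")


_PATH_FIELDS = (
    "synergy", "monotherapy", "targets", "structures", "expression",
    "cell_meta", "out_dir",
)


def load_config(path: Path) -> RunConfig:
    """Load a RunConfig from JSON or YAML; relative paths resolve from the file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    missing = [k for k in _PATH_FIELDS if k not in raw]
    if missing:
        raise ValidationError(f"{path}: missing config keys {missing}")
    base = path.parent
    for key in _PATH_FIELDS:
        raw[key] = (base / raw[key]).resolve()
    if "classifiers" in raw:
        raw["classifiers"] = tuple(raw["classifiers"])
    return RunConfig(**raw)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline for a RunConfig; returns a result summary."""
    from .augmentation import (
        augment_dataset,
        build_substitute_map,
        label_instances,
    )
    from .evaluation import FeatureBuilder, classifier_config, make_folds, run_cv
    from .io_tables import (
        read_tables,
        write_curve,
        write_cutoff_report,
        write_similarity_table,
        write_synergy_table,
    )
    from .similarity import pairwise_similarity_table
    from .threshold import (
        default_grid,
        select_optimal_cutoff,
        substitute_count_curve,
        threshold_curve,
    )

    data = read_tables(
        synergy=cfg.synergy,
        monotherapy=cfg.monotherapy,
        targets=cfg.targets,
        structures=cfg.structures,
        expression=cfg.expression,
        cell_meta=cfg.cell_meta,
        min_target_score=cfg.min_target_score,
    )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = data.drug_records
    used = {d for i in data.instances for d in (i.drug_a, i.drug_b)}
    originals = [r for d, r in records.items() if d in used]
    candidates = [r for d, r in records.items() if d not in used]

    pairs = pairwise_similarity_table(originals, data.profiles, data.universe)
    write_similarity_table(pairs, out / "pairs.tsv", seed=cfg.seed)

    if cfg.dacs_cutoff == "auto":
        grid = default_grid()
        fraction = threshold_curve(pairs, "dacs", grid)
        count = substitute_count_curve(
            originals, candidates, data.profiles, data.universe, grid
        )
        write_curve(fraction, out / "fraction_curve.tsv", seed=cfg.seed)
        write_curve(count, out / "count_curve.tsv", seed=cfg.seed)
        result = select_optimal_cutoff(fraction, count)
        if not result.found:
            raise ValidationError("no curve crossing found; set dacs_cutoff explicitly")
        write_cutoff_report(result, out / "cutoff.json", seed=cfg.seed)
        cutoff = result.dacs_cutoff
    else:
        cutoff = float(cfg.dacs_cutoff)

    subs = build_substitute_map(
        originals, candidates, data.profiles, data.universe, cutoff
    )
    expanded = augment_dataset(data.instances, subs)
    write_synergy_table(expanded, out / "augmented.tsv", seed=cfg.seed)

    labeled, report = label_instances(expanded, syn_cut=cfg.syn_cut,
                                      ant_cut=cfg.ant_cut)
    write_synergy_table(labeled, out / "labeled.tsv", seed=cfg.seed)
    labeled_originals = [i for i in labeled if i.provenance == "original"]
    pool = [i for i in labeled if i.provenance == "augmented"]

    groups = tuple(sorted(set(data.cell_tissue.values())))
    folds = make_folds(
        labeled_originals, cfg.cv_scheme,
        cell_tissue=data.cell_tissue, tissue_groups=groups, seed=cfg.seed,
    )
    builder = FeatureBuilder(
        drug_records=records, expression=data.expression,
        projection_seed=cfg.seed,
    )
    summary: dict = {
        "dacs_cutoff": cutoff,
        "n_original": len(data.instances),
        "n_augmented_total": len(expanded),
        "n_labeled": report.total,
        "evaluations": {},
    }
    rows = []
    for name in cfg.classifiers:
        config = classifier_config(name, **dict(cfg.classifier_overrides))
        for condition in ("original", "augmented"):
            rep = run_cv(folds, labeled_originals, pool, config, condition,
                         builder, seed=cfg.seed)
            summary["evaluations"][f"{name}_{condition}"] = rep.aggregate
            rows.append(rep.to_frame())
    import pandas as pd

    frame = pd.concat(rows, ignore_index=True)
    frame.to_csv(out / "evaluation.tsv", sep="\t", index=False,
                 float_format="%.6f")
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, default=float) + "\n", encoding="utf-8"
    )
    return summary
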