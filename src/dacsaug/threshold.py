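"""Threshold analytics: how similarity relates to shared pharmacology.

Given an all-vs-all similarity table, these operations quantify how the
fraction of drug pairs with positively correlated potency profiles
(Kendall tau > 0) grows with each similarity metric, draw the TC x MCC
heatmap of that fraction, count how many candidate substitutes survive a
DACS threshold, and pick the operating cutoff where the (min-max
normalized) substitute-count curve crosses the positive-fraction curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .similarity import (
    DrugRecord,
    MonotherapyProfile,
    PairSimilarity,
    pair_similarity,
)

__all__ = [
    "ThresholdCurve",
    "HeatmapGrid",
    "CutoffResult",
    "fraction_positive_tau",
    "threshold_curve",
    "dacs_heatmap",
    "substitute_count_curve",
    "select_optimal_cutoff",
    "default_grid",
]

METRICS = ("tc", "mcc", "dacs", "random")


def default_grid(start: float = 0.0, stop: float = 1.42, step: float = 0.01) -> np.ndarray:
    """Default DACS threshold grid: 0 to 1.42 in steps of 0.01."""
    n = int(round((stop - start) / step))
    return np.round(start + step * np.arange(n + 1), 10)


@dataclass(frozen=True)
class ThresholdCurve:
    """Per-threshold fraction of tau-positive pairs and qualifying counts.

    `fraction_positive` is NaN at thresholds where no pair qualifies — an
    explicit undefined marker, not a zero.  For substitute-count curves
    the quantity of interest lives in `n_pairs` and `fraction_positive`
    is all-NaN.
    """

    thresholds: np.ndarray
    fraction_positive: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        f = np.asarray(self.fraction_positive, dtype=float)
        n = np.asarray(self.n_pairs, dtype=np.int64)
        if not (t.shape == f.shape == n.shape):
            raise ValidationError("curve arrays must share one shape")
        if t.size == 0:
            raise ValidationError("empty threshold grid")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("threshold grid must be strictly increasing")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "fraction_positive", f)
        object.__setattr__(self, "n_pairs", n)


def _metric_values(
    pairs: Sequence[PairSimilarity],
    metric: str,
    seed: Optional[int],
) -> np.ndarray:
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if metric == "random":
        rng = np.random.default_rng(0 if seed is None else seed)
        return rng.uniform(0.0, 1.0, size=len(pairs))
    return np.array([getattr(p, metric) for p in pairs], dtype=float)


def fraction_positive_tau(
    pairs: Sequence[PairSimilarity],
    metric: str,
    threshold: float,
    seed: Optional[int] = None,
) -> float:
    """Proportion of pairs with tau strictly > 0 among those with metric >= threshold.

    Returns NaN when no pair qualifies. `metric` is one of tc, mcc, dacs,
    or random (a uniform [0, 1] draw per pair, the null reference).
    """
    values = _metric_values(pairs, metric, seed)
    taus = np.array([p.tau for p in pairs], dtype=float)
    mask = values >= threshold
    if not mask.any():
        return float("nan")
    return float(np.count_nonzero(taus[mask] > 0.0) / np.count_nonzero(mask))


def threshold_curve(
    pairs: Sequence[PairSimilarity],
    metric: str,
    grid: Iterable[float],
    seed: Optional[int] = None,
) -> ThresholdCurve:
    """Sweep `fraction_positive_tau` over an increasing threshold grid.

    For metric="random" one random assignment is drawn per call and reused
    across the whole grid, mirroring a single randomized control curve.
    """
    g = np.asarray(list(grid), dtype=float)
    if g.size == 0:
        raise ValidationError("empty threshold grid")
    values = _metric_values(pairs, metric, seed)
    taus = np.array([p.tau for p in pairs], dtype=float)
    fracs = np.empty_like(g)
    counts = np.empty(g.size, dtype=np.int64)
    for i, t in enumerate(g):
        mask = values >= t
        counts[i] = int(np.count_nonzero(mask))
        fracs[i] = (
            float(np.count_nonzero(taus[mask] > 0.0) / counts[i])
            if counts[i]
            else float("nan")
        )
    return ThresholdCurve(thresholds=g, fraction_positive=fracs, n_pairs=counts)


@dataclass(frozen=True)
class HeatmapGrid:
    """Fraction of tau-positive pairs binned jointly by TC and MCC.

    `fraction` is NaN in empty bins; `tc_hist` / `mcc_hist` are the
    marginal pair counts along each axis.
    """

    tc_edges: np.ndarray
    mcc_edges: np.ndarray
    fraction: np.ndarray
    counts: np.ndarray
    tc_hist: np.ndarray
    mcc_hist: np.ndarray


def dacs_heatmap(
    pairs: Sequence[PairSimilarity],
    tc_bins: Iterable[float],
    mcc_bins: Iterable[float],
) -> HeatmapGrid:
    """2-D histogram of pairs over (TC, MCC) with per-bin tau-positive fraction."""
    tc_edges = np.asarray(list(tc_bins), dtype=float)
    mcc_edges = np.asarray(list(mcc_bins), dtype=float)
    for edges, name in ((tc_edges, "tc_bins"), (mcc_edges, "mcc_bins")):
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValidationError(f"{name} must be increasing with >= 2 edges")
    tc = np.array([p.tc for p in pairs], dtype=float)
    mcc = np.array([p.mcc for p in pairs], dtype=float)
    pos = np.array([p.tau > 0.0 for p in pairs], dtype=float)
    counts, _, _ = np.histogram2d(tc, mcc, bins=(tc_edges, mcc_edges))
    pos_counts, _, _ = np.histogram2d(tc, mcc, bins=(tc_edges, mcc_edges), weights=pos)
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(counts > 0, pos_counts / np.maximum(counts, 1), np.nan)
    tc_hist, _ = np.histogram(tc, bins=tc_edges)
    mcc_hist, _ = np.histogram(mcc, bins=mcc_edges)
    return HeatmapGrid(
        tc_edges=tc_edges,
        mcc_edges=mcc_edges,
        fraction=fraction,
        counts=counts.astype(np.int64),
        tc_hist=tc_hist.astype(np.int64),
        mcc_hist=mcc_hist.astype(np.int64),
    )


def substitute_count_curve(
    originals: Sequence[DrugRecord],
    candidates: Sequence[DrugRecord],
    profiles: Mapping[str, MonotherapyProfile],
    universe: Iterable[str],
    grid: Iterable[float],
) -> ThresholdCurve:
    """Distinct candidates whose best DACS against any original clears each threshold.

    A candidate is counted once per threshold no matter how many originals
    it matches.  Identifier spaces must be disjoint.
    """
    g = np.asarray(list(grid), dtype=float)
    if g.size == 0:
        raise ValidationError("empty threshold grid")
    overlap = {r.drug_id for r in originals} & {r.drug_id for r in candidates}
    if overlap:
        raise ValidationError(
            f"originals and candidates share identifiers: {sorted(overlap)[:5]}"
        )
    uni = frozenset(universe)
    best = np.array(
        [
            max(
                (pair_similarity(orig, cand, profiles, uni).dacs for orig in originals),
                default=float("-inf"),
            )
            for cand in candidates
        ],
        dtype=float,
    )
    counts = np.array([int(np.count_nonzero(best >= t)) for t in g], dtype=np.int64)
    return ThresholdCurve(
        thresholds=g,
        fraction_positive=np.full(g.size, np.nan),
        n_pairs=counts,
    )


@dataclass(frozen=True)
class CutoffResult:
    """Crossing of the normalized substitute-count and positive-fraction curves."""

    found: bool
    dacs_cutoff: float
    fraction_positive_at_cutoff: float
    n_substitutes_at_cutoff: float

    def __post_init__(self) -> None:
        if self.found and not math.isfinite(self.dacs_cutoff):
            raise ValidationError("found cutoff must be finite")


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:  # flat curve: treat as everywhere at its maximum
        return np.ones_like(values, dtype=float)
    return (values - lo) / (hi - lo)


def select_optimal_cutoff(
    fraction_curve: ThresholdCurve, count_curve: ThresholdCurve
) -> CutoffResult:
    """Operating DACS cutoff balancing substitute yield against reliability.

    The substitute-count curve is min-max normalized to [0, 1] and the
    crossing point with the tau-positive-fraction curve is located on the
    shared grid (linear interpolation between adjacent grid points).  With
    several crossings the one at the highest threshold is returned; grid
    points where the fraction is undefined (no qualifying pairs) are
    skipped.
    """
    t = fraction_curve.thresholds
    if t.shape != count_curve.thresholds.shape or np.any(t != count_curve.thresholds):
        raise ValidationError("curves must share one threshold grid")
    f = fraction_curve.fraction_positive
    g = _minmax(count_curve.n_pairs.astype(float))
    d = g - f  # NaN wherever the fraction is undefined

    best_t = None
    for i in range(t.size):
        if math.isnan(d[i]):
            continue
        if d[i] == 0.0:
            best_t = float(t[i])
        elif i + 1 < t.size and not math.isnan(d[i + 1]) and d[i] * d[i + 1] < 0.0:
            frac = d[i] / (d[i] - d[i + 1])
            best_t = float(t[i] + frac * (t[i + 1] - t[i]))
    if best_t is None:
        return CutoffResult(
            found=False,
            dacs_cutoff=float("nan"),
            fraction_positive_at_cutoff=float("nan"),
            n_substitutes_at_cutoff=float("nan"),
        )
    defined = ~np.isnan(f)
    frac_at = float(np.interp(best_t, t[defined], f[defined]))
    count_at = float(np.interp(best_t, t, count_curve.n_pairs.astype(float)))
    return CutoffResult(
        found=True,
        dacs_cutoff=best_t,
        fraction_positive_at_cutoff=frac_at,
        n_substitutes_at_cutoff=count_at,
    )
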