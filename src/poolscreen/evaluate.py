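"""Ground-truth benchmarking: precision-recall, parameter sweeps and the
coverage recommendation.

Because the simulator knows which genes truly carry a fitness effect, any
gene ranking can be scored exactly: precision and recall at every prefix of
the ranking, and "recall at X% precision" — the largest recall achieved by
any prefix whose precision stays at or above X — as the headline metric.
Sweeping simulation parameters (cell-splitting coverage, library width,
doubling time) and re-scoring yields experiment-design guidance, in
particular the minimal coverage at which a target recall is maintained for
a given library width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .params import SimParams
from .pipeline import analyze_screen
from .simulate import run_screen

__all__ = [
    "PRCurve",
    "precision_recall",
    "recall_at_precision",
    "cells_required",
    "simulated_recall",
    "benchmark_grid",
    "recommend_coverage",
    "CoverageRecommendation",
]


@dataclass
class PRCurve:
    """Precision/recall at every prefix of a gene ranking."""

    precision: np.ndarray
    recall: np.ndarray
    n_positives: int


def precision_recall(ranked_genes, truth, positive_class: str) -> PRCurve:
    """Exact PR curve over ranking prefixes.

    ``ranked_genes`` is the gene order (best first); ``truth`` maps every
    gene to its class label.
    """
    truth = pd.Series(truth)
    labels = truth.reindex(ranked_genes)
    if labels.isna().any():
        raise InvalidParameterError("truth labels missing for some ranked genes")
    y = (labels == positive_class).to_numpy()
    n_pos = int(y.sum())
    if n_pos == 0:
        raise InvalidParameterError(f"no genes of class {positive_class!r} in truth")
    tp = np.cumsum(y)
    k = np.arange(1, len(y) + 1)
    return PRCurve(precision=tp / k, recall=tp / n_pos, n_positives=n_pos)


def recall_at_precision(curve: PRCurve, precision_level: float) -> float:
    """Largest recall among prefixes with precision >= the level (0 if none)."""
    if not 0 < precision_level <= 1:
        raise InvalidParameterError("precision_level must be in (0, 1]")
    ok = curve.precision >= precision_level
    return float(curve.recall[ok].max()) if ok.any() else 0.0


def cells_required(n_guides: int, coverage: int) -> int:
    """Cells needed to maintain a mean per-gRNA coverage: the plain product."""
    if n_guides < 1 or coverage < 1:
        raise InvalidParameterError("n_guides and coverage must be positive")
    return int(n_guides) * int(coverage)


def simulated_recall(
    params: SimParams,
    positive_class: str = "negative",
    precision_level: float = 0.99,
    n_perm: int = 1000,
    fix_skew: float | None = None,
    analysis_seed: int | None = None,
) -> float:
    """Simulate one screen, analyze it, and score recall at fixed precision.

    The ranking tail matches the positive class: essential (negative
    fitness) genes are scored on the depletion ranking, growth-suppressing
    (positive fitness) genes on the enrichment ranking.
    """
    sim = run_screen(params)
    res = analyze_screen(
        sim.analysis_counts(aggregate_technical=True),
        n_perm=n_perm,
        seed=analysis_seed if analysis_seed is not None else params.rng_seed,
        fix_skew=fix_skew,
    )
    tail = "depletion" if positive_class == "negative" else "enrichment"
    ranked = res.ranked(tail).index
    return recall_at_precision(
        precision_recall(ranked, sim.truth, positive_class), precision_level
    )


def benchmark_grid(
    param_name: str,
    values,
    base_params: SimParams,
    n_repeats: int = 5,
    seed: int = 0,
    metric=None,
    **metric_kwargs,
) -> pd.DataFrame:
    """Sweep one simulation parameter; evaluate a metric per cell per repeat.

    ``metric(params) -> float`` defaults to :func:`simulated_recall`. Every
    cell records its own derived seed so it can be re-executed exactly.
    Returns a tidy frame: one row per (value, repeat).
    """
    metric = metric or (lambda p: simulated_recall(p, **metric_kwargs))
    root = np.random.SeedSequence(seed)
    rows = []
    for value in values:
        for rep, child in enumerate(root.spawn(n_repeats)):
            cell_seed = int(child.generate_state(1)[0] % (2**31))
            p = base_params.replace(**{param_name: value, "rng_seed": cell_seed})
            rows.append(
                {
                    param_name: value,
                    "repeat": rep,
                    "seed": cell_seed,
                    "metric": float(metric(p)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CoverageRecommendation:
    """Outcome of the minimal-coverage search for one library width."""

    lib_width: float
    recommended: int | None  # None when the target is unreachable on the grid
    target_recall: float
    precision_level: float
    profile: pd.DataFrame = field(repr=False)  # coverage x repeat recalls

    @property
    def max_recall(self) -> float:
        return float(self.profile.groupby("cov_cells")["recall"].mean().max())


def recommend_coverage(
    lib_width: float,
    coverage_grid=(100, 200, 300, 400, 500, 600),
    target_recall: float = 0.95,
    precision_level: float = 0.99,
    base_params: SimParams | None = None,
    n_repeats: int = 5,
    seed: int = 0,
    scorer=None,
    n_perm: int = 1000,
) -> CoverageRecommendation:
    """Smallest cell-splitting coverage that maintains the target recall.

    For each coverage on the (ascending) grid, ``n_repeats`` independent
    screens are simulated at the given library width and scored by recall
    at ``precision_level``; the recommendation is the smallest coverage
    whose mean recall meets ``target_recall``. The full profile is returned
    so the trade-off can be inspected.

    ``scorer(params) -> float`` may replace the simulate-and-analyze
    scorer (used for testing the selection logic in isolation).
    """
    grid = list(coverage_grid)
    if grid != sorted(grid):
        raise InvalidParameterError("coverage grid must be ascending")
    base = base_params or SimParams()
    scorer = scorer or (
        lambda p: simulated_recall(
            p, precision_level=precision_level, n_perm=n_perm
        )
    )
    root = np.random.SeedSequence(seed)
    rows = []
    for cov in grid:
        for rep, child in enumerate(root.spawn(n_repeats)):
            cell_seed = int(child.generate_state(1)[0] % (2**31))
            p = base.replace(
                lib_width=lib_width, cov_cells=cov, rng_seed=cell_seed
            )
            rows.append(
                {
                    "cov_cells": cov,
                    "repeat": rep,
                    "seed": cell_seed,
                    "recall": float(scorer(p)),
                }
            )
    profile = pd.DataFrame(rows)
    means = profile.groupby("cov_cells")["recall"].mean()
    passing = means[means >= target_recall]
    recommended = int(passing.index.min()) if not passing.empty else None
    return CoverageRecommendation(
        lib_width=lib_width,
        recommended=recommended,
        target_recall=target_recall,
        precision_level=precision_level,
        profile=profile,
    )
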