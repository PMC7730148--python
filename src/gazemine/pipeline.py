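"""End-to-end convenience layer: raw library -> representations -> results.

Glues the preprocessing, representation, mining and comparison modules
together for the common workflows (and for the CLI): preprocess every
case of a library, build per-case spatial graphs and Markov models,
assemble distance matrices, run the group comparisons, and mine the
common/contrast patterns between two groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .comparison import distance_matrix, run_comparisons
from .mining import CaseGroup, MiningConfig, TokenCodec, mine_patterns
from .preprocessing import (
    BinnedSequence,
    CaseMeta,
    FixationRoiSequence,
    PreprocessParams,
    ScreenGeometry,
    bin_sequence,
    build_roi_sequence,
    detect_fixations,
    enumerate_subsequences,
)
from .rois import RoiSet
from .spatial import SpatialWeights, build_graph, symmetric_spatial_distance
from .synthetic import CaseLibrary
from .temporal import build_markov, symmetric_temporal_distance

__all__ = [
    "ProcessedCase",
    "preprocess_case",
    "process_library",
    "library_distance_matrices",
    "compare_groups",
    "mine_library",
]


@dataclass(frozen=True)
class ProcessedCase:
    """All derived artifacts of one viewing case."""

    meta: CaseMeta
    sequence: FixationRoiSequence
    binned: BinnedSequence
    pool: frozenset[tuple[str, ...]]


def preprocess_case(
    samples: pd.DataFrame,
    rois: RoiSet,
    geom: ScreenGeometry,
    meta: CaseMeta,
    params: PreprocessParams = PreprocessParams(),
) -> ProcessedCase:
    """Raw samples -> fixations -> ROI sequence -> binned tokens -> pool."""
    fixations = detect_fixations(
        samples,
        geom,
        velocity_threshold=params.velocity_threshold,
        min_dwell=params.min_dwell,
        velocity_window=params.velocity_window,
    )
    seq = build_roi_sequence(fixations, rois, meta)
    binned = bin_sequence(seq, params.bin_window)
    pool = enumerate_subsequences(binned, params.min_len, params.max_len)
    return ProcessedCase(meta=meta, sequence=seq, binned=binned, pool=pool)


def process_library(
    library: CaseLibrary, params: PreprocessParams = PreprocessParams()
) -> list[ProcessedCase]:
    return [
        preprocess_case(c.samples, library.layout, library.geom, c.meta, params)
        for c in library.cases
    ]


def library_distance_matrices(
    cases: Sequence[ProcessedCase],
    rois: Optional[RoiSet] = None,
    weights: SpatialWeights = SpatialWeights(),
    order: int = 1,
    alpha: float = 1e-6,
    metrics: Sequence[str] = ("spatial", "temporal"),
) -> dict[tuple[str, str], np.ndarray]:
    """Symmetrized all-against-all distance matrices, keyed (task, metric).

    Cases are grouped by task; within each task the matrix rows follow
    the input case order.
    """
    by_task: dict[str, list[ProcessedCase]] = {}
    for c in cases:
        by_task.setdefault(c.meta.task_id, []).append(c)
    out: dict[tuple[str, str], np.ndarray] = {}
    for task, task_cases in by_task.items():
        if "spatial" in metrics:
            graphs = [build_graph(c.sequence, rois) for c in task_cases]
            out[(task, "spatial")] = distance_matrix(
                graphs, lambda a, b: symmetric_spatial_distance(a, b, weights)
            )
        if "temporal" in metrics:
            models = [build_markov(c.sequence, order, rois) for c in task_cases]
            out[(task, "temporal")] = distance_matrix(
                models, lambda a, b: symmetric_temporal_distance(a, b, alpha)
            )
    return out


def compare_groups(
    cases: Sequence[ProcessedCase],
    rois: Optional[RoiSet] = None,
    weights: SpatialWeights = SpatialWeights(),
    order: int = 1,
    alpha: float = 1e-6,
    metrics: Sequence[str] = ("spatial", "temporal"),
    sig_level: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Distance matrices + Mann-Whitney tests in one call."""
    matrices = library_distance_matrices(cases, rois, weights, order, alpha, metrics)
    case_groups: dict[str, list[str]] = {}
    for c in cases:
        case_groups.setdefault(c.meta.task_id, []).append(c.meta.group_id)
    return run_comparisons(matrices, case_groups, alpha=sig_level, adjust=adjust)


def mine_library(
    cases: Sequence[ProcessedCase],
    group_a: str,
    group_b: str,
    config: MiningConfig = MiningConfig(),
):
    """Mine common/contrast patterns between two groups of processed cases.

    Returns ``(common, contrast_a, contrast_b)``.
    """
    codec = TokenCodec([])
    seqs: dict[str, dict[str, BinnedSequence]] = {group_a: {}, group_b: {}}
    for c in cases:
        if c.meta.group_id in seqs:
            seqs[c.meta.group_id][c.meta.case_id] = c.binned
    for gid in (group_a, group_b):
        if not seqs[gid]:
            raise ValueError(f"no cases for group {gid!r}")
    ga = CaseGroup(group_a, seqs[group_a], config, codec=codec)
    gb = CaseGroup(group_b, seqs[group_b], config, codec=codec)
    return mine_patterns(ga, gb, config)
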