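"""All-against-all distance distributions and Mann-Whitney group tests.

The discrimination protocol compares viewing cases at the distribution
level: for a task, every unordered pair of cases gets a (symmetrized)
spatial or temporal distance; the within-group distances of a reference
group (e.g. expert-expert, "EE") are then tested against the
between-group distances to another group (e.g. expert-novice, "EN")
with the two-sided Mann-Whitney U test, which makes no distributional
assumption.  A p-value below 0.05 flags the two distance distributions
as statistically different.

Caveat: pairwise distances within a distribution share cases and are
therefore not independent; the test is applied to them as-is (the
standard practice for this protocol), so p-values are descriptive
rather than exactly calibrated.  Raw p-values are reported without
multiplicity correction; a Benjamini-Hochberg column is available as
optional extra output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MannWhitneyResult",
    "mannwhitney_u",
    "distance_matrix",
    "distance_distributions",
    "run_comparisons",
]


class MannWhitneyResult(NamedTuple):
    u: float
    p: float
    degenerate: bool = False


def mannwhitney_u(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with tie correction.

    Uses the exact null distribution when both samples have at most 8
    values and no ties are present, and the normal approximation with
    continuity correction otherwise.  Two identical constant samples are
    flagged degenerate with p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=len(x) * len(y) / 2.0, p=1.0, degenerate=True)
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue))


def distance_matrix(
    items: Sequence, pairwise: Callable[[object, object], float]
) -> np.ndarray:
    """Symmetric distance matrix with zero diagonal.

    ``pairwise`` should already be symmetrized (e.g. the mean of the two
    directed spatial or temporal distances).
    """
    n = len(items)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise(items[i], items[j])
    return mat


def distance_distributions(
    matrix: np.ndarray, groups: Sequence[str]
) -> dict[tuple, np.ndarray]:
    """Pool pairwise distances into within- and between-group multisets.

    Returns a dict keyed by ``("within", g)`` (all unordered intra-group
    pairs, self-pairs excluded) and ``("between", g, h)`` for g < h (all
    cross pairs).
    """
    matrix = np.asarray(matrix)
    n = len(groups)
    if matrix.shape != (n, n):
        raise ValueError("matrix shape does not match group labels")
    out: dict[tuple, list[float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = groups[i], groups[j]
            if gi == gj:
                key = ("within", gi)
            else:
                key = ("between", *sorted((gi, gj)))
            out.setdefault(key, []).append(matrix[i, j])
    return {k: np.asarray(v) for k, v in out.items()}


@dataclass(frozen=True)
class ComparisonSpec:
    """One test: distribution ``x`` vs distribution ``y`` (keys as in
    :func:`distance_distributions`), labelled ``name``."""

    name: str
    x_key: tuple
    y_key: tuple


def baseline_protocol(baseline: str, others: Sequence[str]) -> list[ComparisonSpec]:
    """Within-baseline vs between(baseline, other), for each other group.

    This is the "EE vs EN"-style protocol: the internal consistency of
    the reference group against its distances to each comparison group.
    """
    specs = []
    for g in others:
        specs.append(
            ComparisonSpec(
                name=f"{baseline}{baseline}/{baseline}{g}",
                x_key=("within", baseline),
                y_key=("between", *sorted((baseline, g))),
            )
        )
    return specs


def run_comparisons(
    matrices: Mapping[tuple[str, str], np.ndarray],
    case_groups: Mapping[str, Sequence[str]],
    specs: Optional[Mapping[str, Sequence[ComparisonSpec]] | Sequence[ComparisonSpec]] = None,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Run Mann-Whitney tests over distance distributions.

    Parameters
    ----------
    matrices
        ``(task, metric) -> symmetric distance matrix`` (metric is
        ``"spatial"`` or ``"temporal"``).
    case_groups
        ``task -> group label per case`` in matrix order.
    specs
        Comparison specs, either one list applied to every task or a
        ``task -> list`` mapping.  Defaults to the baseline protocol of
        the first group label against each other group.
    alpha
        Significance level for the ``significant`` flag.
    adjust
        Add a Benjamini-Hochberg adjusted column ``p_bh``.

    Returns a tidy DataFrame with columns task, metric, comparison, n1,
    n2, U, p, significant (and optionally p_bh).  A comparison whose
    within-group side has fewer than two cases is skipped with a
    warning.
    """
    rows = []
    for (task, metric), matrix in matrices.items():
        groups = list(case_groups[task])
        dists = distance_distributions(matrix, groups)
        if specs is None:
            order = list(dict.fromkeys(groups))
            task_specs = baseline_protocol(order[0], order[1:])
        elif isinstance(specs, Mapping):
            task_specs = list(specs[task])
        else:
            task_specs = list(specs)
        for spec in task_specs:
            if spec.x_key not in dists or spec.y_key not in dists:
                warnings.warn(
                    f"task {task}: comparison {spec.name} skipped "
                    "(a distribution has no pairs)"
                )
                continue
            x, y = dists[spec.x_key], dists[spec.y_key]
            res = mannwhitney_u(x, y)
            rows.append(
                {
                    "task": task,
                    "metric": metric,
                    "comparison": spec.name,
                    "n1": len(x),
                    "n2": len(y),
                    "U": res.u,
                    "p": res.p,
                    "significant": res.p < alpha,
                }
            )
    report = pd.DataFrame(rows)
    if adjust and len(report) > 0:
        from statsmodels.stats.multitest import multipletests

        report["p_bh"] = multipletests(report["p"], method="fdr_bh")[1]
    return report
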