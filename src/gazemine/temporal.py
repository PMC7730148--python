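"""Temporal representation: dwell-weighted Markov chains and KL distance.

The temporal signature of a case is an n-th order Markov chain over the
image's ROI set (n <= 5, reflecting the ~4-item capacity of visual
working memory).  The initial vector ``pi`` is a point mass on the ROI
of the first fixation (the first n-gram for higher orders).  Transition
weights fold dwell time into the usual frequency estimate:

    A[h -> l_j] = count(h -> l_j) / count(h -> any) * dwell_weight(last(h))

where ``dwell_weight(l)`` is the ROI's share of the case's total dwell.
Rows therefore sum to the dwell weight of the history's last ROI, not to
one; the structure is a dwell-weighted transition profile rather than a
stochastic matrix.

The temporal distance between two cases flattens each model (transition
weights concatenated with ``pi``) over the union of both key sets, adds
a small smoothing constant to every coordinate, renormalizes to a
probability vector, and applies Kullback-Leibler divergence (natural
log, so values are in nats).  Like KL itself the distance is asymmetric;
:func:`symmetric_temporal_distance` averages both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .preprocessing import FixationRoiSequence
from .rois import RoiSet

__all__ = [
    "MarkovModel",
    "build_markov",
    "temporal_distance",
    "symmetric_temporal_distance",
]

MAX_ORDER = 5

History = tuple[str, ...]


@dataclass(frozen=True)
class MarkovModel:
    """Sparse n-th order dwell-weighted Markov representation of a case."""

    order: int
    states: tuple[str, ...]
    pi: dict[History, float] = field(default_factory=dict)
    transitions: dict[History, dict[str, float]] = field(default_factory=dict)

    def flatten_keys(self) -> set[tuple]:
        """Keys of the flattened vector: pi entries and (history, next) pairs."""
        keys: set[tuple] = {("pi", h) for h in self.pi}
        for h, row in self.transitions.items():
            keys.update(("A", h, j) for j in row)
        return keys

    def flat_value(self, key: tuple) -> float:
        if key[0] == "pi":
            return self.pi.get(key[1], 0.0)
        return self.transitions.get(key[1], {}).get(key[2], 0.0)

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "states": list(self.states),
            "pi": {" ".join(h): p for h, p in self.pi.items()},
            "transitions": {
                " ".join(h): dict(row) for h, row in self.transitions.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkovModel":
        return cls(
            order=d["order"],
            states=tuple(d["states"]),
            pi={tuple(h.split(" ")): p for h, p in d["pi"].items()},
            transitions={
                tuple(h.split(" ")): dict(row) for h, row in d["transitions"].items()
            },
        )


def build_markov(
    seq: FixationRoiSequence, order: int = 1, rois: Optional[RoiSet] = None
) -> MarkovModel:
    """Build the dwell-weighted Markov model of a case.

    ``rois`` fixes the full state set of the image (including unvisited
    ROIs); without it the visited labels are used.  A sequence shorter
    than ``order + 1`` yields a model with ``pi`` only and no
    transitions; for a sequence shorter than ``order`` the initial key is
    the whole available prefix.
    """
    if not 1 <= order <= MAX_ORDER:
        raise ValueError(f"order must be in [1, {MAX_ORDER}]")
    labels = seq.labels
    states = rois.labels if rois is not None else tuple(sorted(set(labels)))

    pi: dict[History, float] = {}
    if labels:
        pi[labels[: min(order, len(labels))]] = 1.0

    dwell: dict[str, float] = {}
    for f in seq.fixations:
        dwell[f.roi_label] = dwell.get(f.roi_label, 0.0) + f.dwell  # type: ignore[index]
    total_dwell = sum(dwell.values())

    counts: dict[History, dict[str, int]] = {}
    for i in range(len(labels) - order):
        h = labels[i : i + order]
        nxt = labels[i + order]
        counts.setdefault(h, {})
        counts[h][nxt] = counts[h].get(nxt, 0) + 1

    transitions: dict[History, dict[str, float]] = {}
    for h, row in counts.items():
        out = sum(row.values())
        dw = dwell.get(h[-1], 0.0) / total_dwell if total_dwell > 0 else 0.0
        transitions[h] = {j: c / out * dw for j, c in row.items()}
    return MarkovModel(order=order, states=states, pi=pi, transitions=transitions)


def _smoothed_vectors(
    m1: MarkovModel, m2: MarkovModel, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    keys = sorted(m1.flatten_keys() | m2.flatten_keys())
    v1 = np.array([m1.flat_value(k) for k in keys], dtype=float) + alpha
    v2 = np.array([m2.flat_value(k) for k in keys], dtype=float) + alpha
    return v1 / v1.sum(), v2 / v2.sum()


def temporal_distance(m1: MarkovModel, m2: MarkovModel, alpha: float = 1e-6) -> float:
    """KL divergence between the flattened, smoothed model vectors (nats).

    Both vectors are laid out over the union of the two models' keys,
    shifted by ``alpha`` on every coordinate and renormalized, so the
    divergence is finite and well defined even for disjoint supports.
    Raises ``ValueError`` on an order mismatch.
    """
    if m1.order != m2.order:
        raise ValueError(f"order mismatch: {m1.order} vs {m2.order}")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    p, q = _smoothed_vectors(m1, m2, alpha)
    if len(p) == 0:
        return 0.0
    return float(np.sum(p * np.log(p / q)))


def symmetric_temporal_distance(
    m1: MarkovModel, m2: MarkovModel, alpha: float = 1e-6
) -> float:
    """Mean of the two directed KL divergences; used for distance matrices."""
    return 0.5 * (temporal_distance(m1, m2, alpha) + temporal_distance(m2, m1, alpha))
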