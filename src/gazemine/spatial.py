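"""Spatial representation of a viewing case and the subgraph distance.

A case's spatial signature is an undirected simple graph ``G = (V, E)``:
one vertex per visited ROI (carrying its fixation count and total dwell),
one edge per direct ROI transition observed anywhere in the scanpath.
Self-transitions and duplicate edges are trimmed.  Edge weights —
``(dwell(u) + dwell(v)) * transition_count(u, v)`` — are kept for export
and inspection but do not enter the distance.

The distance between two cases is an approximate subgraph-alignment
score: a weighted sum of

* ``d_struct``  — fraction of G1 edges without a counterpart in G2,
* ``d_node``    — per-matched-node discrepancy in fixation count and
  dwell, normalized by G1 totals,
* ``d_node_gaps`` — mean gap penalty of G1 nodes with no counterpart,

where the node correspondence ``lambda: V1 -> V2`` matches identical
labels first and then ROIs of the same ontology class.  The raw distance
is asymmetric in (G1, G2); :func:`symmetric_spatial_distance` averages
both directions for use in distance matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .preprocessing import FixationRoiSequence
from .rois import RoiSet

__all__ = [
    "SpatialWeights",
    "build_graph",
    "build_node_mapping",
    "struct_distance",
    "node_distance",
    "node_gap_distance",
    "spatial_distance",
    "symmetric_spatial_distance",
]


@dataclass(frozen=True)
class SpatialWeights:
    """Component weights of the spatial distance.

    ``w_e`` (structure), ``w_n`` (matched nodes) and ``w_g`` (absent
    nodes) default to 1/3 each; within the node component, fixation-count
    and dwell discrepancies are mixed with ``w_f`` and ``w_d`` (1/2 each).
    """

    w_e: float = 1.0 / 3.0
    w_n: float = 1.0 / 3.0
    w_g: float = 1.0 / 3.0
    w_f: float = 0.5
    w_d: float = 0.5

    def __post_init__(self) -> None:
        if min(self.w_e, self.w_n, self.w_g, self.w_f, self.w_d) < 0:
            raise ValueError("spatial weights must be non-negative")


def build_graph(seq: FixationRoiSequence, rois: Optional[RoiSet] = None) -> nx.Graph:
    """Build the undirected simple graph of a fixation-ROI sequence.

    Node attributes: ``num_fixations``, ``dwell_ms`` and, when ``rois``
    is given, ``gap_penalty`` and ``ontology_class``.  Edge attributes:
    ``transitions`` (count of A->B plus B->A adjacencies) and ``weight``
    = (dwell(A)+dwell(B)) * transitions.
    """
    g = nx.Graph(case_id=seq.meta.case_id)
    labels = seq.labels
    for f in seq.fixations:
        lab = f.roi_label
        if lab in g:
            g.nodes[lab]["num_fixations"] += 1
            g.nodes[lab]["dwell_ms"] += f.dwell
        else:
            g.add_node(lab, num_fixations=1, dwell_ms=float(f.dwell))
    for a, b in zip(labels, labels[1:]):
        if a == b:
            continue  # self-loops trimmed
        if g.has_edge(a, b):
            g.edges[a, b]["transitions"] += 1
        else:
            g.add_edge(a, b, transitions=1)
    for a, b, data in g.edges(data=True):
        data["weight"] = (g.nodes[a]["dwell_ms"] + g.nodes[b]["dwell_ms"]) * data["transitions"]
    if rois is not None:
        for lab in g.nodes:
            g.nodes[lab]["gap_penalty"] = rois[lab].gap_penalty
            if rois[lab].ontology_class is not None:
                g.nodes[lab]["ontology_class"] = rois[lab].ontology_class
    return g


def build_node_mapping(g1: nx.Graph, g2: nx.Graph) -> dict[str, str]:
    """Injective node correspondence ``lambda`` from G1 into G2.

    Identical labels are matched first; remaining G1 nodes are matched to
    an unused G2 node of the same ``ontology_class``.  When several
    candidates share the class, the one with the most similar total dwell
    wins (ties by label order).
    """
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for u in sorted(g1.nodes):
        if u in g2:
            mapping[u] = u
            used.add(u)
    for u in sorted(g1.nodes):
        if u in mapping:
            continue
        oc = g1.nodes[u].get("ontology_class")
        if oc is None:
            continue
        candidates = [
            v
            for v in sorted(g2.nodes)
            if v not in used and g2.nodes[v].get("ontology_class") == oc
        ]
        if not candidates:
            continue
        dwell_u = g1.nodes[u]["dwell_ms"]
        best = min(candidates, key=lambda v: (abs(g2.nodes[v]["dwell_ms"] - dwell_u), v))
        mapping[u] = best
        used.add(best)
    return mapping


def struct_distance(g1: nx.Graph, g2: nx.Graph, mapping: dict[str, str]) -> float:
    """Fraction of G1 edges unmatched in G2 under ``mapping``.

    An edge (u, v) of G1 is matched iff both endpoints are mapped and
    (lambda u, lambda v) is an edge of G2.  Returns 0 when G1 has no
    edges (documented convention).
    """
    m1 = g1.number_of_edges()
    if m1 == 0:
        return 0.0
    unmatched = sum(
        1
        for u, v in g1.edges
        if not (u in mapping and v in mapping and g2.has_edge(mapping[u], mapping[v]))
    )
    return unmatched / m1


def node_distance(
    g1: nx.Graph,
    g2: nx.Graph,
    mapping: dict[str, str],
    w_f: float = 0.5,
    w_d: float = 0.5,
) -> float:
    """Attribute discrepancy over matched nodes.

    Sums, over matched G1 nodes u, the absolute fixation-count difference
    normalized by G1's total fixation count (weight ``w_f``) plus the
    absolute dwell difference normalized by G1's total dwell (``w_d``).
    """
    total_fix = sum(d["num_fixations"] for _, d in g1.nodes(data=True))
    total_dwell = sum(d["dwell_ms"] for _, d in g1.nodes(data=True))
    if total_fix == 0 or total_dwell == 0:
        if g1.number_of_nodes() > 0:
            warnings.warn("node_distance: zero total fixations or dwell in G1; returning 0")
        return 0.0
    acc = 0.0
    for u, v in mapping.items():
        d_att = abs(g1.nodes[u]["num_fixations"] - g2.nodes[v]["num_fixations"]) / total_fix
        d_dur = abs(g1.nodes[u]["dwell_ms"] - g2.nodes[v]["dwell_ms"]) / total_dwell
        acc += w_f * d_att + w_d * d_dur
    return acc


def node_gap_distance(g1: nx.Graph, mapping: dict[str, str]) -> float:
    """Mean gap penalty of G1 nodes absent from the correspondence."""
    n1 = g1.number_of_nodes()
    if n1 == 0:
        return 0.0
    gap_sum = sum(
        g1.nodes[u].get("gap_penalty", 1.0) for u in g1.nodes if u not in mapping
    )
    return gap_sum / n1


def spatial_distance(
    g1: nx.Graph,
    g2: nx.Graph,
    weights: SpatialWeights = SpatialWeights(),
    mapping: Optional[dict[str, str]] = None,
) -> float:
    """Directed spatial distance ``SD(G1, G2)``: weighted component sum."""
    if mapping is None:
        mapping = build_node_mapping(g1, g2)
    return (
        weights.w_e * struct_distance(g1, g2, mapping)
        + weights.w_n * node_distance(g1, g2, mapping, weights.w_f, weights.w_d)
        + weights.w_g * node_gap_distance(g1, mapping)
    )


def symmetric_spatial_distance(
    g1: nx.Graph, g2: nx.Graph, weights: SpatialWeights = SpatialWeights()
) -> float:
    """Mean of the two directed distances; used for distance matrices."""
    return 0.5 * (spatial_distance(g1, g2, weights) + spatial_distance(g2, g1, weights))
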