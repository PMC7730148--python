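"""Common and contrast visual-reasoning pattern mining.

After preprocessing, every case is a binned token sequence; all of its
contiguous windows with length in ``[min_len, max_len]`` form the case's
subsequence pool, and the pools of a viewer group are stacked into a
:class:`CaseGroup`.  Mining compares two groups:

* **support** of a candidate subsequence ``p`` in a group is the
  fraction of cases whose pool holds at least one window within
  Levenshtein distance ``theta`` of ``p`` — a similar-but-inexact window
  still counts, absorbing micro-saccades and stray fixations;
* **growth** of ``p`` from its own group against the other group is
  ``supp_own / max_q supp(q, other)`` over the theta-similar windows
  ``q`` of the other group's pool, or infinity when no similar window
  exists there;
* a **common pattern** passes the support threshold ``rho`` in both
  groups with growth below ``epsilon`` in both directions; a **contrast
  pattern** for a group is drawn from that group's own pool, passes
  ``rho`` there, and has growth >= ``epsilon``.

Mined patterns are original windows of real scanpaths, never
abstractions, so each can be replayed and interpreted on the stimulus.

Levenshtein distances run through ``edlib`` after packing ROI tokens
into single bytes (alphabets beyond 255 labels are rejected).  Several
exactness-preserving shortcuts keep mining fast: windows whose length
differs from the candidate's by more than ``theta`` are skipped (the
length difference lower-bounds the distance); case-level presence is
screened with an exact-substring check and an infix alignment of the
candidate against the whole binned string (the unconstrained infix
distance lower-bounds every window-constrained distance); and growth
denominators are found by a descending-support scan with a symbol-count
feasibility bound.  Equivalence with exhaustive enumeration is asserted
in the test suite.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np

from .preprocessing import BinnedSequence

__all__ = [
    "MiningConfig",
    "CaseGroup",
    "Pattern",
    "PatternSet",
    "PatternStatistics",
    "levenshtein",
    "support",
    "growth",
    "mine_patterns",
    "roi_distance",
    "pattern_statistics",
]

Tokens = tuple[str, ...]


@dataclass(frozen=True)
class MiningConfig:
    """Mining thresholds.

    ``theta``: Levenshtein tolerance for "similar" subsequences (default
    2); ``rho``: support threshold (default 0.2); ``epsilon``: growth
    threshold (default 2); ``min_len``/``max_len``: window lengths kept
    in the pools (defaults 4 and 16 tokens).
    """

    theta: int = 2
    rho: float = 0.2
    epsilon: float = 2.0
    min_len: int = 4
    max_len: int = 16

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if self.epsilon <= 1:
            raise ValueError("epsilon must be > 1")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("need 1 <= min_len <= max_len")


class TokenCodec:
    """Packs ROI labels into single bytes for edlib."""

    def __init__(self, labels: Iterable[str]):
        self._index: dict[str, int] = {}
        for lab in labels:
            self.add(lab)

    def add(self, label: str) -> None:
        if label not in self._index:
            if len(self._index) >= 255:
                raise ValueError("token alphabet larger than 255 labels")
            self._index[label] = len(self._index)

    def encode(self, tokens: Sequence[str]) -> bytes:
        idx = self._index
        for lab in tokens:
            if lab not in idx:
                self.add(lab)
        return bytes(idx[lab] for lab in tokens)


def levenshtein(a: Sequence[str], b: Sequence[str]) -> int:
    """Unit-cost edit distance between two ROI token sequences."""
    if len(a) == 0 or len(b) == 0:
        return max(len(a), len(b))
    codec = TokenCodec(list(a) + list(b))
    return edlib.align(codec.encode(a), codec.encode(b), mode="NW")["editDistance"]


@dataclass
class _Case:
    case_id: str
    tokens: Tokens
    encoded: bytes


class CaseGroup:
    """The binned sequences and subsequence pools of one viewer group."""

    def __init__(
        self,
        group_id: str,
        sequences: Mapping[str, BinnedSequence] | Mapping[str, Sequence[str]],
        config: MiningConfig = MiningConfig(),
        codec: Optional[TokenCodec] = None,
    ):
        if len(sequences) == 0:
            raise ValueError("a CaseGroup needs at least one case")
        self.group_id = group_id
        self.config = config
        self.codec = codec if codec is not None else TokenCodec([])
        self.cases: list[_Case] = []
        for case_id, seq in sequences.items():
            tokens = tuple(seq.tokens) if isinstance(seq, BinnedSequence) else tuple(seq)
            self.cases.append(_Case(case_id, tokens, self.codec.encode(tokens)))

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def pool(self, case: _Case) -> frozenset[Tokens]:
        cfg = self.config
        toks = case.tokens
        out: set[Tokens] = set()
        for length in range(cfg.min_len, min(cfg.max_len, len(toks)) + 1):
            for start in range(len(toks) - length + 1):
                out.add(toks[start : start + length])
        return frozenset(out)

    def pooled_subsequences(self) -> frozenset[Tokens]:
        """Distinct windows across all cases of the group."""
        out: set[Tokens] = set()
        for case in self.cases:
            out |= self.pool(case)
        return frozenset(out)

    # -- presence ---------------------------------------------------------

    def _present_in_case(self, enc_p: bytes, case: _Case, theta: int) -> bool:
        """Exact test: does the case's pool hold a window within theta of p?"""
        cfg = self.config
        lo = max(cfg.min_len, len(enc_p) - theta)
        hi = min(cfg.max_len, len(enc_p) + theta)
        s = case.encoded
        if hi > len(s):
            hi = len(s)
        if lo > hi:
            return False
        if lo <= len(enc_p) <= hi and enc_p in s:
            return True  # exact window; cheap substring precheck
        res = edlib.align(enc_p, s, mode="HW", task="locations", k=theta)
        if res["editDistance"] == -1:
            return False
        for start, end in res["locations"]:
            start = 0 if start is None else start
            if lo <= end - start + 1 <= hi:
                return True
        # All optimal infix spans fall outside the pooled window lengths;
        # fall back to an exact window scan (rare).
        for length in range(lo, hi + 1):
            for st in range(len(s) - length + 1):
                if (
                    edlib.align(enc_p, s[st : st + length], mode="NW", k=theta)["editDistance"]
                    != -1
                ):
                    return True
        return False

    def presence_count(self, p: Sequence[str], theta: int) -> int:
        enc = self.codec.encode(p)
        return sum(self._present_in_case(enc, c, theta) for c in self.cases)


def support(p: Sequence[str], group: CaseGroup, theta: int = 2) -> float:
    """Fraction of the group's cases containing a theta-similar window of p."""
    return group.presence_count(p, theta) / group.n_cases


def growth(
    p: Sequence[str],
    own: CaseGroup,
    other: CaseGroup,
    theta: int = 2,
    supp_own: Optional[float] = None,
    other_supports: Optional[Mapping[Tokens, float]] = None,
) -> float:
    """Support ratio of p in its own group against the other group.

    The denominator is the maximum support among the other group's
    pooled windows within Levenshtein distance ``theta`` of ``p``
    (equivalently, the growth is the minimum ratio over all similar
    matches).  Returns ``inf`` when no similar window exists in the
    other pool.  Precomputed supports may be supplied to avoid
    rescanning.
    """
    if supp_own is None:
        supp_own = support(p, own, theta)
    if other_supports is None:
        other_supports = {
            q: support(q, other, theta) for q in other.pooled_subsequences()
        }
    best = _max_similar_support(tuple(p), other_supports, other.codec, theta)
    if best is None:
        return math.inf
    return supp_own / best


def _max_similar_support(
    p: Tokens,
    supports: Mapping[Tokens, float],
    codec: TokenCodec,
    theta: int,
    ordered: Optional[list[tuple[Tokens, bytes, float]]] = None,
) -> Optional[float]:
    """Max support among theta-similar sequences, or None if none exist.

    When ``ordered`` (sequences with encodings, sorted by support
    descending) is given, the scan stops at the first similar match —
    exact, since supports only decrease down the list.
    """
    enc_p = codec.encode(p)
    if ordered is None:
        ordered = sorted(
            ((q, codec.encode(q), s) for q, s in supports.items()),
            key=lambda item: -item[2],
        )
    for q, enc_q, supp_q in ordered:
        if abs(len(enc_q) - len(enc_p)) > theta:
            continue
        if edlib.align(enc_p, enc_q, mode="NW", k=theta)["editDistance"] != -1:
            return supp_q
    return None


@dataclass(frozen=True)
class Pattern:
    """A mined subsequence with its support/growth annotations."""

    tokens: Tokens
    kind: str  # "common" | "contrast"
    source_group: str
    supp_own: float
    supp_other: float
    growth: float  # may be math.inf

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class PatternSet:
    kind: str
    group_id: str
    patterns: list[Pattern] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def token_sets(self) -> set[Tokens]:
        return {p.tokens for p in self.patterns}


def mine_patterns(
    g1: CaseGroup, g2: CaseGroup, config: Optional[MiningConfig] = None
) -> tuple[PatternSet, PatternSet, PatternSet]:
    """Mine common and contrast patterns between two viewer groups.

    Candidates are the distinct pooled windows (contrast candidates for a
    group come from that group's own pool; common candidates from the
    union).  Returns ``(common, contrast_g1, contrast_g2)``.
    """
    if config is None:
        config = g1.config
    theta, rho, eps = config.theta, config.rho, config.epsilon
    if g1.codec is not g2.codec:
        # re-encode group 2 under a shared codec so byte comparisons align
        g2 = CaseGroup(
            g2.group_id,
            {c.case_id: c.tokens for c in g2.cases},
            g2.config,
            codec=g1.codec,
        )
    codec = g1.codec

    pool1 = g1.pooled_subsequences()
    pool2 = g2.pooled_subsequences()
    candidates = pool1 | pool2
    encoded = {p: codec.encode(p) for p in candidates}
    supp1 = {p: g1.presence_count(p, theta) / g1.n_cases for p in candidates}
    supp2 = {p: g2.presence_count(p, theta) / g2.n_cases for p in candidates}

    # Growth denominators: per-length buckets of the other group's pool,
    # sorted by support descending.  Candidates are pre-screened with a
    # symbol-count bound (one edit changes the count vector by at most 2
    # in L1, so L1 > 2*theta rules similarity out) and the merged scan
    # stops at the first verified similar match, which attains the
    # maximum support.  Both devices are exact.
    n_alpha = max(max(enc) for enc in encoded.values() if enc) + 1

    def _count_vector(enc: bytes) -> np.ndarray:
        return np.bincount(
            np.frombuffer(enc, dtype=np.uint8), minlength=n_alpha
        ).astype(np.int16)

    def length_buckets(pool: frozenset[Tokens], supp: Mapping[Tokens, float]):
        grouped: dict[int, list[Tokens]] = {}
        for q in pool:
            grouped.setdefault(len(q), []).append(q)
        buckets = {}
        for length, qs in grouped.items():
            encs = np.array([encoded[q] for q in qs], dtype=object)
            counts = np.stack([_count_vector(e) for e in encs])
            buckets[length] = (np.array([supp[q] for q in qs]), encs, counts)
        return buckets

    buckets2 = length_buckets(pool2, supp2)
    buckets1 = length_buckets(pool1, supp1)

    def grow(p: Tokens, supp_own: float, buckets_other) -> float:
        enc_p = encoded[p]
        pv = _count_vector(enc_p)
        cand_supps, cand_encs = [], []
        for length in range(len(enc_p) - theta, len(enc_p) + theta + 1):
            if length not in buckets_other:
                continue
            supp_arr, encs, counts = buckets_other[length]
            feasible = np.abs(counts - pv).sum(axis=1) <= 2 * theta
            if feasible.any():
                cand_supps.append(supp_arr[feasible])
                cand_encs.append(encs[feasible])
        if not cand_supps:
            return math.inf
        supps = np.concatenate(cand_supps)
        encs = np.concatenate(cand_encs)
        for i in np.argsort(-supps, kind="stable"):
            if edlib.align(enc_p, encs[i], mode="NW", k=theta)["editDistance"] != -1:
                return supp_own / float(supps[i])
        return math.inf

    common = PatternSet("common", f"{g1.group_id}+{g2.group_id}")
    contrast1 = PatternSet("contrast", g1.group_id)
    contrast2 = PatternSet("contrast", g2.group_id)

    for p in sorted(candidates):
        s1, s2 = supp1[p], supp2[p]
        need_g1 = s1 >= rho  # growth vs g2 needed
        need_g2 = s2 >= rho
        gr1 = grow(p, s1, buckets2) if need_g1 else None
        gr2 = grow(p, s2, buckets1) if need_g2 else None
        if need_g1 and need_g2 and gr1 < eps and gr2 < eps:
            src = "both" if p in pool1 and p in pool2 else (
                g1.group_id if p in pool1 else g2.group_id
            )
            common.patterns.append(
                Pattern(p, "common", src, s1, s2, max(gr1, gr2))
            )
        if need_g1 and gr1 >= eps and p in pool1:
            contrast1.patterns.append(Pattern(p, "contrast", g1.group_id, s1, s2, gr1))
        if need_g2 and gr2 >= eps and p in pool2:
            contrast2.patterns.append(Pattern(p, "contrast", g2.group_id, s2, s1, gr2))
    return common, contrast1, contrast2


def roi_distance(p: Sequence[str], q: Sequence[str]) -> float:
    """Cosine bag-of-ROI distance in [0, 1]: order-free dissimilarity."""
    if len(p) == 0 or len(q) == 0:
        raise ValueError("roi_distance requires non-empty patterns")
    bp, bq = Counter(p), Counter(q)
    labels = set(bp) | set(bq)
    v1 = np.array([bp.get(l, 0) for l in labels], dtype=float)
    v2 = np.array([bq.get(l, 0) for l in labels], dtype=float)
    cos = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return 1.0 - cos


@dataclass(frozen=True)
class PatternStatistics:
    """Summary of a pattern set (the per-group report columns)."""

    n_patterns: int
    mean_length: float
    max_length: int
    mean_pairwise_lev: float
    mean_pairwise_roi: float
    mean_support: float
    pct_unique: float  # % of patterns with infinite growth


def pattern_statistics(ps: PatternSet) -> PatternStatistics:
    """Compute the summary statistics of a mined pattern set.

    Pairwise means are over unordered pattern pairs (no self-pairs); an
    empty set yields an all-zero record.
    """
    pats = ps.patterns
    n = len(pats)
    if n == 0:
        return PatternStatistics(0, 0.0, 0, 0.0, 0.0, 0.0, 0.0)
    lengths = [len(p) for p in pats]
    lev_sum = roi_sum = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            lev_sum += levenshtein(pats[i].tokens, pats[j].tokens)
            roi_sum += roi_distance(pats[i].tokens, pats[j].tokens)
            pairs += 1
    return PatternStatistics(
        n_patterns=n,
        mean_length=float(np.mean(lengths)),
        max_length=max(lengths),
        mean_pairwise_lev=lev_sum / pairs if pairs else 0.0,
        mean_pairwise_roi=roi_sum / pairs if pairs else 0.0,
        mean_support=float(np.mean([p.supp_own for p in pats])),
        pct_unique=100.0 * sum(math.isinf(p.growth) for p in pats) / n,
    )
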