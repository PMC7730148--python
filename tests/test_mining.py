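"""Levenshtein tolerance mining: support, growth, pattern sets, statistics."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazemine import (
    CaseGroup,
    MiningConfig,
    PatternSet,
    growth,
    levenshtein,
    mine_patterns,
    pattern_statistics,
    roi_distance,
    support,
)
from gazemine.mining import Pattern, TokenCodec

# ---------------------------------------------------------------------------
# Independent oracles


def lev_oracle(a, b) -> int:
    """Textbook dynamic-programming edit distance."""
    m, n = len(a), len(b)
    d = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        d[i][0] = i
    for j in range(n + 1):
        d[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d[i][j] = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return d[m][n]


def windows_oracle(tokens, min_len, max_len):
    out = set()
    for i in range(len(tokens)):
        for j in range(i + min_len, min(i + max_len, len(tokens)) + 1):
            out.add(tuple(tokens[i:j]))
    return out


def mine_oracle(tokens1, tokens2, cfg: MiningConfig):
    """Exhaustive evaluation of the support/growth set definitions."""
    pools1 = [windows_oracle(t, cfg.min_len, cfg.max_len) for t in tokens1]
    pools2 = [windows_oracle(t, cfg.min_len, cfg.max_len) for t in tokens2]
    union1 = set().union(*pools1) if pools1 else set()
    union2 = set().union(*pools2) if pools2 else set()

    def supp(p, pools):
        hits = sum(any(lev_oracle(p, w) <= cfg.theta for w in pool) for pool in pools)
        return hits / len(pools)

    def grow(p, pools_own, union_other, pools_other):
        similar = [q for q in union_other if lev_oracle(p, q) <= cfg.theta]
        if not similar:
            return math.inf
        return supp(p, pools_own) / max(supp(q, pools_other) for q in similar)

    common, contrast1, contrast2 = {}, {}, {}
    for p in union1 | union2:
        s1, s2 = supp(p, pools1), supp(p, pools2)
        g1 = grow(p, pools1, union2, pools2) if s1 > 0 else None
        g2 = grow(p, pools2, union1, pools1) if s2 > 0 else None
        if s1 >= cfg.rho and s2 >= cfg.rho and g1 < cfg.epsilon and g2 < cfg.epsilon:
            common[p] = (s1, s2)
        if s1 >= cfg.rho and g1 >= cfg.epsilon and p in union1:
            contrast1[p] = (s1, g1)
        if s2 >= cfg.rho and g2 >= cfg.epsilon and p in union2:
            contrast2[p] = (s2, g2)
    return common, contrast1, contrast2


def make_group(gid, token_strings, cfg, codec=None):
    return CaseGroup(
        gid,
        {f"{gid}{i}": tuple(tok) for i, tok in enumerate(token_strings)},
        cfg,
        codec=codec,
    )


# ---------------------------------------------------------------------------


class TestLevenshtein:
    def test_examples(self):
        assert levenshtein(("A", "A", "B"), ("A", "A", "B")) == 0
        assert levenshtein(("A", "A", "B"), ("A", "B", "B")) == 1
        assert levenshtein(("A", "A", "B", "C"), ()) == 4

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.lists(st.sampled_from("ABCD"), max_size=12),
        b=st.lists(st.sampled_from("ABCD"), max_size=12),
    )
    def test_matches_dp_oracle(self, a, b):
        assert levenshtein(tuple(a), tuple(b)) == lev_oracle(a, b)

    def test_metric_axioms_on_random_triples(self):
        """Symmetry and the triangle inequality hold on 1000 random
        token triples."""
        rng = np.random.default_rng(23)
        labels = list("ABCDE")
        for _ in range(1000):
            a, b, c = (
                tuple(labels[i] for i in rng.integers(0, 5, size=rng.integers(0, 9)))
                for _ in range(3)
            )
            dab, dba = levenshtein(a, b), levenshtein(b, a)
            assert dab == dba
            assert levenshtein(a, c) <= dab + levenshtein(b, c)
            assert (dab == 0) == (a == b)


class TestSupport:
    def test_universal_pattern_has_support_one(self):
        cfg = MiningConfig(min_len=3, max_len=6)
        g = make_group("g", ["AABXY", "ZAABW", "QAAB"], cfg)
        assert support(("A", "A", "B"), g, theta=0) == 1.0

    def test_exact_substring_scan_example(self):
        """theta=0 support equals exact substring containment: AAB appears
        in 3 of the 5 cases."""
        cfg = MiningConfig(min_len=3, max_len=4)
        g = make_group("g", ["AABC", "CAAB", "BBBB", "ABAB", "AABA"], cfg)
        assert support(("A", "A", "B"), g, theta=0) == pytest.approx(0.6)

    def test_disjoint_alphabet_zero(self):
        cfg = MiningConfig(min_len=3, max_len=4)
        g = make_group("g", ["AABC", "CAAB"], cfg)
        assert support(("X", "Y", "Z"), g, theta=2) == 0.0

    @settings(derandomize=True, max_examples=40)
    @given(data=st.data())
    def test_support_matches_bruteforce_and_is_monotone_in_theta(self, data):
        cfg = MiningConfig(min_len=3, max_len=5)
        cases = data.draw(
            st.lists(st.text(alphabet="ABC", min_size=3, max_size=12), min_size=1, max_size=5)
        )
        p = tuple(data.draw(st.text(alphabet="ABC", min_size=3, max_size=5)))
        g = make_group("g", cases, cfg)
        pools = [windows_oracle(c, cfg.min_len, cfg.max_len) for c in cases]
        prev = -1.0
        for theta in (0, 1, 2, 3):
            brute = sum(
                any(lev_oracle(p, w) <= theta for w in pool) for pool in pools
            ) / len(pools)
            s = support(p, g, theta)
            assert s == pytest.approx(brute)
            assert s >= prev  # monotone non-decreasing in theta
            prev = s


class TestGrowth:
    def test_infinite_when_no_similar_subsequence(self):
        cfg = MiningConfig(min_len=3, max_len=4)
        own = make_group("a", ["XXXX", "XXXY"], cfg)
        other = make_group("b", ["AABC", "CAAB"], cfg, codec=own.codec)
        assert growth(("X", "X", "X", "X"), own, other, theta=2) == math.inf

    def test_ratio_against_maximum_support_similar_match(self):
        """supp_own 0.6 against a best similar match of 0.25 gives 2.4,
        verified by enumerating all similar matches by brute force."""
        cfg = MiningConfig(min_len=4, max_len=4)
        own = make_group(
            "a", ["AABB", "AABB", "AABB", "CCCC", "DDDD"], cfg
        )  # supp(AABB) = 3/5
        other = make_group(
            "b", ["AABX", "EEEE", "EEEE", "EEEE"], cfg, codec=own.codec
        )  # best similar match AABX with supp 1/4
        p = ("A", "A", "B", "B")
        sim = [
            q
            for q in other.pooled_subsequences()
            if lev_oracle(p, q) <= 2
        ]
        best = max(support(q, other, 2) for q in sim)
        assert best == pytest.approx(0.25)
        assert growth(p, own, other, theta=2) == pytest.approx(0.6 / 0.25)

    def test_identical_groups_growth_one(self):
        cfg = MiningConfig(min_len=3, max_len=5)
        cases = ["ABCAB", "BCABC"]
        own = make_group("a", cases, cfg)
        other = make_group("b", cases, cfg, codec=own.codec)
        for p in own.pooled_subsequences():
            assert growth(p, own, other, theta=0) == pytest.approx(1.0)


class TestMinePatterns:
    def test_identical_single_case_groups_all_common(self):
        cfg = MiningConfig(min_len=3, max_len=4, rho=0.2, epsilon=2.0, theta=1)
        codec = TokenCodec([])
        g1 = make_group("a", ["ABCD"], cfg, codec)
        g2 = make_group("b", ["ABCD"], cfg, codec)
        common, c1, c2 = mine_patterns(g1, g2, cfg)
        assert common.token_sets() == g1.pooled_subsequences()
        assert len(c1) == 0 and len(c2) == 0

    def test_planted_contrast_with_infinite_growth(self):
        cfg = MiningConfig(min_len=4, max_len=6, rho=0.2, epsilon=2.0, theta=2)
        codec = TokenCodec([])
        planted = "XYXYXY"
        g1 = make_group("a", [planted + "AB", "AB" + planted, "ABABAB", planted, "BABA"], cfg, codec)
        g2 = make_group("b", ["ABABAB", "BABABA", "AABBAA"], cfg, codec)
        _, c1, _ = mine_patterns(g1, g2, cfg)
        hit = [p for p in c1 if p.tokens == tuple(planted)]
        assert hit and math.isinf(hit[0].growth)
        assert hit[0].supp_own >= 0.6

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_equals_exhaustive_oracle_on_random_libraries(self, seed):
        """Mined sets equal the exhaustive support/growth enumeration on
        random libraries (<= 8 cases, sequences <= 20 tokens): exact set
        equality plus matching supports and growths."""
        rng = np.random.default_rng(seed)
        cfg = MiningConfig(
            theta=int(rng.integers(1, 3)),
            rho=0.25,
            epsilon=2.0,
            min_len=3,
            max_len=int(rng.integers(4, 7)),
        )
        alphabet = "ABCDE"[: rng.integers(2, 6)]

        def random_cases(n):
            return [
                "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=rng.integers(6, 21)))
                for _ in range(n)
            ]

        t1, t2 = random_cases(rng.integers(2, 5)), random_cases(rng.integers(2, 5))
        codec = TokenCodec([])
        g1, g2 = make_group("a", t1, cfg, codec), make_group("b", t2, cfg, codec)
        common, c1, c2 = mine_patterns(g1, g2, cfg)
        o_common, o_c1, o_c2 = mine_oracle(t1, t2, cfg)

        assert common.token_sets() == set(o_common)
        assert c1.token_sets() == set(o_c1)
        assert c2.token_sets() == set(o_c2)
        for p in common:
            s1, s2 = o_common[p.tokens]
            assert p.supp_own == pytest.approx(s1)
            assert p.supp_other == pytest.approx(s2)
        for ps, oracle in ((c1, o_c1), (c2, o_c2)):
            for p in ps:
                s, g = oracle[p.tokens]
                assert p.supp_own == pytest.approx(s)
                assert p.growth == g if math.isinf(g) else p.growth == pytest.approx(g)

    def test_common_and_contrast_disjoint_and_verbatim(self):
        rng = np.random.default_rng(9)
        cfg = MiningConfig(min_len=3, max_len=5, theta=1, rho=0.3)
        t1 = ["ABCAB", "CABCA", "BCABC"]
        t2 = ["ACBAC", "CBACB", "ABCBA"]
        codec = TokenCodec([])
        g1, g2 = make_group("a", t1, cfg, codec), make_group("b", t2, cfg, codec)
        common, c1, c2 = mine_patterns(g1, g2, cfg)
        assert not (common.token_sets() & c1.token_sets())
        assert not (common.token_sets() & c2.token_sets())
        for p in c1:
            assert any(p.tokens in windows_oracle(t, cfg.min_len, cfg.max_len) for t in t1)
        for p in c2:
            assert any(p.tokens in windows_oracle(t, cfg.min_len, cfg.max_len) for t in t2)


class TestRoiDistance:
    def test_identical_bags_zero(self):
        assert roi_distance(("A", "B", "A"), ("A", "A", "B")) == pytest.approx(0.0)

    def test_disjoint_label_sets_one(self):
        assert roi_distance(("A", "A"), ("B", "C")) == pytest.approx(1.0)

    def test_hand_cosine(self):
        # bags (2,1) vs (1,2): 1 - 4/5
        assert roi_distance(("A", "A", "B"), ("A", "B", "B")) == pytest.approx(0.2)

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            roi_distance((), ("A",))


class TestPatternStatistics:
    def test_single_pattern(self):
        ps = PatternSet("contrast", "g", [
            Pattern(("A",) * 5, "contrast", "g", 0.4, 0.0, math.inf)
        ])
        st_ = pattern_statistics(ps)
        assert st_.n_patterns == 1
        assert st_.mean_length == 5 and st_.max_length == 5
        assert st_.mean_pairwise_lev == 0.0 and st_.mean_pairwise_roi == 0.0
        assert st_.mean_support == pytest.approx(0.4)
        assert st_.pct_unique == pytest.approx(100.0)

    def test_equal_lengths_make_max_equal_mean(self):
        ps = PatternSet("contrast", "g", [
            Pattern(("A", "B", "C"), "contrast", "g", 0.5, 0.1, 5.0),
            Pattern(("B", "C", "A"), "contrast", "g", 0.3, 0.1, 3.0),
        ])
        st_ = pattern_statistics(ps)
        assert st_.max_length == st_.mean_length == 3

    def test_empty_set_all_zero(self):
        st_ = pattern_statistics(PatternSet("common", "g"))
        assert st_.n_patterns == 0 and st_.mean_support == 0.0

    def test_random_sets_match_direct_recomputation(self):
        rng = np.random.default_rng(31)
        pats = []
        for i in range(6):
            toks = tuple("ABCD"[j] for j in rng.integers(0, 4, size=rng.integers(3, 8)))
            gr = math.inf if rng.random() < 0.5 else float(rng.uniform(2, 9))
            pats.append(Pattern(toks, "contrast", "g", float(rng.uniform(0.2, 1)), 0.0, gr))
        st_ = pattern_statistics(PatternSet("contrast", "g", pats))
        pairs = list(itertools.combinations(pats, 2))
        assert st_.mean_pairwise_lev == pytest.approx(
            np.mean([lev_oracle(a.tokens, b.tokens) for a, b in pairs])
        )
        assert st_.mean_pairwise_roi == pytest.approx(
            np.mean([roi_distance(a.tokens, b.tokens) for a, b in pairs])
        )
        assert st_.mean_support == pytest.approx(np.mean([p.supp_own for p in pats]))
        assert st_.pct_unique == pytest.approx(
            100 * np.mean([math.isinf(p.growth) for p in pats])
        )
        assert st_.max_length == max(len(p) for p in pats)
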