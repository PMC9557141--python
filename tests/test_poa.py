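"""Partial-order alignment graph, alignment DP and consensus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longstr import PoaScores, align_to_graph, build_graph, consensus, consensus_of

SCORES = PoaScores(match=2, mismatch=-4, gap=-4)


def path_score(graph, seq, path, scores=SCORES):
    total = 0
    for node, i in path:
        if node is not None and i is not None:
            b, c = graph.bases[node], seq[i]
            total += scores.match if (b == c and b != "N") else scores.mismatch
        else:
            total += scores.gap
    return total


def chain_graph(seq, n=1):
    return build_graph([seq] * n, SCORES)


class TestAlign:
    def test_identity_alignment_scores_all_matches(self):
        g = chain_graph("ACGT")
        path = align_to_graph(g, "ACGT", SCORES)
        assert path_score(g, "ACGT", path) == 4 * SCORES.match
        assert all(v is not None and i is not None for v, i in path)

    def test_single_mismatch(self):
        g = chain_graph("ACGT")
        path = align_to_graph(g, "ACTT", SCORES)
        assert path_score(g, "ACTT", path) == 3 * SCORES.match + SCORES.mismatch

    def test_two_deletions(self):
        g = chain_graph("AAAA")
        path = align_to_graph(g, "AA", SCORES)
        assert path_score(g, "AA", path) == 2 * SCORES.match + 2 * SCORES.gap

    def test_alignment_is_optimal_against_exhaustive_oracle(self):
        # a linear graph reduces POA to pairwise global alignment, which a
        # tiny recursive oracle can score exhaustively
        def brute(a, b):
            if not a:
                return SCORES.gap * len(b)
            if not b:
                return SCORES.gap * len(a)
            sub = SCORES.match if a[0] == b[0] else SCORES.mismatch
            return max(
                sub + brute(a[1:], b[1:]),
                SCORES.gap + brute(a[1:], b),
                SCORES.gap + brute(a, b[1:]),
            )

        rng = np.random.default_rng(3)
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), rng.integers(1, 8)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(1, 8)))
            g = chain_graph(a)
            path = align_to_graph(g, b, SCORES)
            assert path_score(g, b, path) == brute(a, b)


class TestBuild:
    def test_identical_inputs_make_a_weighted_chain(self):
        g = chain_graph("ACGT", n=3)
        assert len(g) == 4
        assert g.weights == [3, 3, 3, 3]

    def test_single_mismatch_creates_branch(self):
        g = build_graph(["ACGT", "AGGT"], SCORES)
        assert len(g) == 5
        assert sorted(g.weights) == [1, 1, 2, 2, 2]

    def test_single_input_chain(self):
        g = chain_graph("TTAG")
        assert len(g) == 4
        assert g.weights == [1, 1, 1, 1]

    def test_every_input_is_spelled_by_some_path(self):
        seqs = ["ACGTACG", "ACGAACG", "ACGTCG"]
        g = build_graph(seqs, SCORES)
        spelled = set()

        def walk(v, prefix):
            prefix = prefix + g.bases[v]
            if not g.edges_out[v]:
                spelled.add(prefix)
                return
            for w in g.edges_out[v]:
                walk(w, prefix)

        for v in g.sources():
            walk(v, "")
        assert set(seqs) <= spelled


class TestConsensus:
    def test_identity_for_all_n(self):
        for n in (1, 2, 5):
            assert consensus_of(["ACGTTGCA"] * n).sequence == "ACGTTGCA"

    def test_majority_vote(self):
        res = consensus_of(["ACGT", "ACGT", "ACTT"])
        assert res.sequence == "ACGT"
        assert res.n_inputs == 3

    def test_base_tie_break(self):
        assert consensus_of(["AC", "AG"]).sequence == "AC"

    def test_majority_recovery_distinct_errors(self):
        # 2k+1 copies, k of them each carrying one substitution at a
        # distinct position: the clean sequence must win everywhere
        s = "ACGTACGTACGTACGTACGT"
        for k in (1, 2, 3):
            copies = [s] * (k + 1)
            for j in range(k):
                pos = 3 * j
                alt = "T" if s[pos] != "T" else "G"
                copies.append(s[:pos] + alt + s[pos + 1:])
            assert consensus_of(copies).sequence == s

    def test_substitution_noise_recovery(self):
        # miniature of the seeded recovery study documented in the
        # acceptance suite
        rng = np.random.default_rng(11)
        s = "".join(rng.choice(list("ACGT"), 100))
        copies = []
        for _ in range(10):
            arr = list(s)
            for h in np.flatnonzero(rng.random(100) < 0.02):
                arr[h] = "ACGT"[("ACGT".index(arr[h]) + rng.integers(1, 4)) % 4]
            copies.append("".join(arr))
        res = consensus_of(copies)
        assert res.sequence == s
        assert res.mean_support > 8

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_graph([], SCORES)
        with pytest.raises(ValueError):
            build_graph(["", ""], SCORES)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    seq=st.text(alphabet="ACGT", min_size=1, max_size=30),
    n=st.integers(1, 5),
)
def test_consensus_of_identical_copies_is_identity(seq, n):
    assert consensus_of([seq] * n).sequence == seq
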