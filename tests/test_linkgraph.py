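import pytest

from _oracles import (
    best_connection_oracle,
    count_oracle,
    link_scores_oracle,
    retention_oracle,
)
from conftest import random_pairs, random_scaffolds
from triscaf import (
    ScaffoldNode,
    WindowParams,
    best_connection,
    build_graph,
    count_end_links,
    end_distance,
    link_scores,
    window_cv,
)
from triscaf.io_formats import ContactPair
from triscaf.linkgraph import EndPairCounts, PairArrays, count_all_end_links


class TestEndDistance:
    @pytest.mark.parametrize("pos,end,length,expected", [
        (0, "B", 100, 0),
        (0, "E", 100, 99),
        (99, "E", 100, 0),
        (42, "B", 100, 42),
    ])
    def test_terminal_geometry(self, pos, end, length, expected):
        assert end_distance(pos, length, end) == expected

    def test_matches_definition_on_random_inputs(self, rng):
        for _ in range(200):
            length = rng.randint(1, 10_000)
            pos = rng.randrange(length)
            assert end_distance(pos, length, "B") == pos
            assert end_distance(pos, length, "E") == length - 1 - pos

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            end_distance(100, 100, "B")


class TestCountEndLinks:
    def test_no_pairs(self):
        i = ScaffoldNode.from_contig("a", 100)
        j = ScaffoldNode.from_contig("b", 100)
        assert count_end_links([], i, j, 10) == EndPairCounts(0, 0, 0, 0)

    def test_forced_corner_geometry(self):
        # loci at E of i and B of j: only the EB window holds at l=10
        i = ScaffoldNode.from_contig("a", 100)
        j = ScaffoldNode.from_contig("b", 100)
        pairs = [ContactPair.make("a", 99, "b", 0)]
        got = count_end_links(pairs, i, j, 10)
        assert (got.n_eb, got.n_bb, got.n_be, got.n_ee) == (1, 0, 0, 0)

    def test_same_scaffold_pairs_ignored(self):
        i = ScaffoldNode.from_contig("a", 100)
        j = ScaffoldNode.from_contig("b", 100)
        pairs = [ContactPair.make("a", 1, "a", 2)]
        assert count_end_links(pairs, i, j, 100) == EndPairCounts(0, 0, 0, 0)

    @pytest.mark.parametrize("window", ["triangle", "square"])
    def test_matches_bruteforce_enumeration(self, rng, window):
        for _ in range(10):
            scaffolds = random_scaffolds(rng, 2)
            pairs = random_pairs(rng, scaffolds, 500)
            l = rng.randint(1, 600)
            got = count_end_links(pairs, scaffolds[0], scaffolds[1], l, window)
            assert got.as_dict() == count_oracle(pairs, scaffolds[0],
                                                 scaffolds[1], l, window)

    def test_symmetry_under_swap(self, rng):
        for _ in range(10):
            scaffolds = random_scaffolds(rng, 2)
            pairs = random_pairs(rng, scaffolds, 300)
            l = rng.randint(1, 500)
            ij = count_end_links(pairs, scaffolds[0], scaffolds[1], l)
            ji = count_end_links(pairs, scaffolds[1], scaffolds[0], l)
            assert ij == ji.transpose()

    def test_monotone_in_l_and_triangle_within_square(self, rng):
        scaffolds = random_scaffolds(rng, 2)
        pairs = random_pairs(rng, scaffolds, 400)
        prev = EndPairCounts()
        for l in (10, 50, 100, 200, 500):
            tri = count_end_links(pairs, scaffolds[0], scaffolds[1], l)
            sq = count_end_links(pairs, scaffolds[0], scaffolds[1], l, "square")
            for lab in ("BB", "BE", "EB", "EE"):
                assert prev.as_dict()[lab] <= tri.as_dict()[lab] <= sq.as_dict()[lab]
            prev = tri

    def test_vectorized_counts_agree_with_per_pair_path(self, rng):
        scaffolds = random_scaffolds(rng, 6)
        pairs = random_pairs(rng, scaffolds, 800)
        contig_ids = [c.contig_id for s in scaffolds for c in s.components]
        arrays = PairArrays.from_pairs(pairs, contig_ids)
        bulk = count_all_end_links(scaffolds, arrays, 300)
        for si in range(len(scaffolds)):
            for sj in range(si + 1, len(scaffolds)):
                slow = count_end_links(pairs, scaffolds[si], scaffolds[sj], 300)
                assert bulk.get((si, sj), EndPairCounts()) == slow


class TestBestConnection:
    @pytest.mark.parametrize("counts,expected", [
        ((1, 2, 7, 3), (7, "EB")),
        ((0, 0, 0, 0), (0, "EB")),       # all-tie: preference order
        ((5, 5, 5, 5), (5, "EB")),
        ((9, 5, 5, 5), (9, "BB")),
    ])
    def test_argmax_and_tie_rule(self, counts, expected):
        assert best_connection(EndPairCounts(*counts)) == expected

    def test_matches_bruteforce(self, rng):
        for _ in range(300):
            c = {lab: rng.randint(0, 50) for lab in ("BB", "BE", "EB", "EE")}
            got = best_connection(EndPairCounts(c["BB"], c["BE"], c["EB"], c["EE"]))
            assert got == best_connection_oracle(c)


class TestLinkScores:
    def test_printed_normalization(self):
        cands = [(f"p{k}", n) for k, n in enumerate([10, 5, 3, 1, 1])]
        got = [w for _, w in link_scores(cands)]
        assert got == pytest.approx([0.50, 0.25, 0.15, 0.05, 0.05])

    def test_single_candidate(self):
        assert link_scores([("p", 7)]) == [("p", 1.0)]

    def test_all_zero_candidates(self):
        assert link_scores([("a", 0), ("b", 0)]) == [("a", 0.0), ("b", 0.0)]

    def test_topk_selection_matches_bruteforce(self, rng):
        for _ in range(100):
            cands = [(f"p{k}", rng.randint(0, 30)) for k in range(8)]
            assert link_scores(cands) == link_scores_oracle(cands)

    def test_nonzero_scores_sum_to_one(self, rng):
        for _ in range(100):
            cands = [(f"p{k}", rng.randint(0, 9)) for k in range(rng.randint(1, 8))]
            scores = link_scores(cands)
            if any(n for _, n in cands):
                assert sum(w for _, w in scores) == pytest.approx(1.0)


def _junction_pairs(a, b, n, near=30):
    """n pairs concentrated at E of contig a facing B of contig b."""
    out = []
    for k in range(n):
        out.append(ContactPair.make(a.id, a.length - 1 - (k % near),
                                    b.id, k % near))
    return out


class TestBuildGraph:
    def test_one_strong_link(self):
        a, b = (ScaffoldNode.from_contig(x, 200) for x in "ab")
        pairs = _junction_pairs(a, b, 50)
        g = build_graph([a, b], pairs, WindowParams(l=100))
        assert len(g.edges) == 1 and g.edges[0].label == "EB"

    def test_per_end_uniqueness(self):
        # b and c both court the E end of a; only the stronger survives
        a, b, c = (ScaffoldNode.from_contig(x, 200) for x in "abc")
        pairs = _junction_pairs(a, b, 60) + _junction_pairs(a, c, 30)
        g = build_graph([a, b, c], pairs, WindowParams(l=100, w_min=0.0))
        ends_of_a = [e.end_of("a") for e in g.edges_of("a")]
        assert ends_of_a.count("E") <= 1
        assert any(e.other("a") == "b" for e in g.edges_of("a"))

    def test_cutoff_removes_weak_edges(self):
        a, b = (ScaffoldNode.from_contig(x, 200) for x in "ab")
        pairs = _junction_pairs(a, b, 10)
        assert build_graph([a, b], pairs, WindowParams(l=100, w_min=0.2)).edges
        # a strong third partner dilutes the a-b score below the cutoff
        c = ScaffoldNode.from_contig("c", 200)
        pairs += _junction_pairs(a, c, 500, near=90)
        g = build_graph([a, b, c], pairs, WindowParams(l=100, w_min=0.2))
        assert not any({e.i, e.j} == {"a", "b"} for e in g.edges)

    def test_degree_bounds_and_oracle_equivalence(self, rng):
        for trial in range(8):
            scaffolds = random_scaffolds(rng, rng.randint(5, 20))
            pairs = random_pairs(rng, scaffolds, 2000)
            params = WindowParams(l=rng.randint(50, 500),
                                  w_min=rng.choice([0.0, 0.1, 0.2, 0.3]))
            g = build_graph(scaffolds, pairs, params)
            # invariant: one edge per node end
            seen_ends = set()
            for e in g.edges:
                for node in (e.i, e.j):
                    key = (node, e.end_of(node))
                    assert key not in seen_ends
                    seen_ends.add(key)
                assert e.w_i >= params.w_min and e.w_j >= params.w_min
            # equivalence with the independent retention oracle
            ids = [s.id for s in scaffolds]
            cands = {}
            for si in range(len(scaffolds)):
                for sj in range(si + 1, len(scaffolds)):
                    c = count_oracle(pairs, scaffolds[si], scaffolds[sj], params.l)
                    n, lab = best_connection_oracle(c)
                    if n > 0:
                        cands[(si, sj)] = (n, lab)
            expect = retention_oracle(cands, ids, params.w_min)
            got = {(ids.index(e.i), ids.index(e.j)) for e in g.edges}
            assert got == expect


class TestWindowCV:
    def _two_contigs(self):
        return (ScaffoldNode.from_contig("a", 1000),
                ScaffoldNode.from_contig("b", 1000))

    def test_uniform_density_low_cv(self, rng):
        a, b = self._two_contigs()
        pairs = [ContactPair.make("a", rng.randrange(1000),
                                  "b", rng.randrange(1000)) for _ in range(20_000)]
        cv_tri, cv_sq = window_cv(pairs, a, b, 1000, bins=4)
        assert cv_tri < 0.2 and cv_sq < 0.2

    def test_far_corner_block_inflates_square_cv(self, rng):
        a, b = self._two_contigs()
        pairs = [ContactPair.make("a", rng.randrange(1000),
                                  "b", rng.randrange(1000)) for _ in range(2000)]
        # long-range block: far from both ends => far corner of the square
        pairs += [ContactPair.make("a", 1000 - 1 - rng.randrange(900, 1000),
                                   "b", rng.randrange(900, 1000))
                  for _ in range(2000)]
        cv_tri, cv_sq = window_cv(pairs, a, b, 1000, bins=10)
        assert cv_sq > cv_tri

    def test_empty_window(self):
        a, b = self._two_contigs()
        assert window_cv([], a, b, 100, bins=4) == (0.0, 0.0)
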