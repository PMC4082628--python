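"""Alignment and clustering contracts, each checked against an independent
oracle: a quadratic Gotoh DP for local alignment scores, brute-force
all-pairs thresholding for edges, and union-find for single linkage."""

import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from reducto import orthology
from reducto.orthology import (AlignmentHit, ClusterParams, ProteinRecord,
                               cluster_single_linkage, hit_qualifies,
                               local_align, partition_core, similarity_edges)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


def mutate_protein(rng, seq, n_subs):
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_subs, replace=False):
        chars[pos] = rng.choice([a for a in AA if a != chars[pos]])
    return "".join(chars)


def gotoh_local_score(a, b, open_cost=12.0, extend_cost=1.0):
    """Quadratic-space affine local alignment oracle (first gap character
    costs ``open_cost``, each further one ``extend_cost``)."""
    mat = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                                       Iy[i - 1, j - 1]))
            Ix[i, j] = max(M[i - 1, j] - open_cost, Ix[i - 1, j] - extend_cost)
            Iy[i, j] = max(M[i, j - 1] - open_cost, Iy[i, j - 1] - extend_cost)
            best = max(best, M[i, j])
    return best


class TestLocalAlign:
    def test_identical_sequences(self, rng):
        seq = random_protein(rng, 100)
        a = ProteinRecord("s1", "p1", seq)
        b = ProteinRecord("s2", "p2", seq)
        hit = local_align(a, b)
        assert hit.identity == 1.0
        assert hit.longest_coverage == 1.0

    def test_score_matches_dp_oracle(self, rng):
        for _ in range(8):
            a = random_protein(rng, int(rng.integers(20, 51)))
            if rng.random() < 0.5:
                b = mutate_protein(rng, a, int(rng.integers(1, 8)))
            else:
                b = random_protein(rng, int(rng.integers(20, 51)))
            hit = local_align(ProteinRecord("x", "a", a),
                              ProteinRecord("y", "b", b))
            assert hit.score == pytest.approx(gotoh_local_score(a, b))

    def test_symmetry(self, rng):
        a = ProteinRecord("x", "a", random_protein(rng, 80))
        b = ProteinRecord("y", "b", mutate_protein(rng, a.sequence, 10))
        h1 = local_align(a, b)
        h2 = local_align(b, a)
        assert h1.score == h2.score
        assert h1.identity == pytest.approx(h2.identity)
        assert h1.longest_coverage == pytest.approx(h2.longest_coverage)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ProteinRecord("s", "p", "")

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ValueError, match="matrix"):
            ClusterParams(matrix_name="NOSUCH99")


class TestSimilarityEdges:
    def test_identity_boundary_is_strict(self):
        hit = AlignmentHit("a", "b", 100, 50, 1e-10, identity=0.78,
                           longest_coverage=0.9, query_interval=(0, 10),
                           subject_interval=(0, 10))
        assert not hit_qualifies(hit, ClusterParams())
        barely = AlignmentHit("a", "b", 100, 50, 1e-10, identity=0.781,
                              longest_coverage=0.9, query_interval=(0, 10),
                              subject_interval=(0, 10))
        assert hit_qualifies(barely, ClusterParams())

    def test_exact_078_identity_sequence_pair_makes_no_edge(self, rng):
        # 100 aa, 22 conservative substitutions spread through the middle:
        # the optimal local alignment is the gap-free full overlap, identity
        # exactly 0.78, which the strict threshold must refuse
        conservative = {"D": "E", "E": "D", "K": "R", "R": "K", "I": "V", "V": "I"}
        base = "".join(rng.choice(list(conservative), size=100))
        chars = list(base)
        for pos in np.linspace(3, 96, 22).astype(int):
            chars[pos] = conservative[chars[pos]]
        other = "".join(chars)
        a = ProteinRecord("s1", "a", base)
        b = ProteinRecord("s2", "b", other)
        hit = local_align(a, b)
        assert hit.identity == pytest.approx(0.78)
        assert not hit_qualifies(hit, ClusterParams())

    def test_identical_proteomes_link_across_strains(self, rng):
        seqs = [random_protein(rng, 120) for _ in range(10)]
        prots = [ProteinRecord(s, f"{s}|p{i}", seq)
                 for s in ("s1", "s2") for i, seq in enumerate(seqs)]
        edges = similarity_edges(prots)
        cross = [(u, v) for u, v, _ in edges]
        assert len(cross) >= 10

    def test_pseudo_flagged_input_rejected(self):
        p = ProteinRecord("s", "p", "MKVL", is_pseudo=True)
        with pytest.raises(ValueError, match="non-pseudogene"):
            similarity_edges([p])

    def test_edges_equal_bruteforce(self, rng):
        prots = []
        for i in range(15):
            seq = random_protein(rng, int(rng.integers(80, 140)))
            prots.append(ProteinRecord(f"s{i % 3}", f"p{i:02d}", seq))
            if i % 3 == 0:  # a diverged sibling that should link
                sib = mutate_protein(rng, seq, max(1, len(seq) // 12))
                prots.append(ProteinRecord("sx", f"q{i:02d}", sib))
        params = ClusterParams()
        fast = {frozenset((u, v)) for u, v, _ in similarity_edges(prots, params)}
        db = sum(len(p.sequence) for p in prots)
        brute = set()
        for i in range(len(prots)):
            for j in range(i + 1, len(prots)):
                hit = local_align(prots[i], prots[j], params,
                                  search_space=len(prots[i].sequence) * db)
                if hit_qualifies(hit, params):
                    brute.add(frozenset((prots[i].protein_id, prots[j].protein_id)))
        assert fast == brute
        assert brute  # the planted siblings actually produce edges


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


class TestClustering:
    def test_no_edges_gives_singletons(self):
        prots = [ProteinRecord("s", f"p{i}", "MKVL") for i in range(5)]
        groups = cluster_single_linkage(prots, [])
        assert len(groups) == 5
        assert all(len(g.members) == 1 for g in groups)

    def test_single_linkage_transitivity(self):
        prots = [ProteinRecord("s", p, "MKVL") for p in "abc"]
        groups = cluster_single_linkage(prots, [("a", "b"), ("b", "c")])
        assert len(groups) == 1
        assert {pid for _, pid in groups[0].members} == {"a", "b", "c"}

    def test_dangling_edge_rejected(self):
        prots = [ProteinRecord("s", "a", "MKVL")]
        with pytest.raises(ValueError, match="unknown protein"):
            cluster_single_linkage(prots, [("a", "zzz")])

    def test_random_graphs_match_unionfind_oracle(self):
        rnd = random.Random(7)
        for _ in range(20):
            n = rnd.randint(2, 60)
            names = [f"p{i:02d}" for i in range(n)]
            prots = [ProteinRecord("s", p, "MKVL") for p in names]
            edges = [(rnd.choice(names), rnd.choice(names))
                     for _ in range(rnd.randint(0, 2 * n))]
            edges = [(u, v) for u, v in edges if u != v]
            groups = cluster_single_linkage(prots, edges)
            uf = _UnionFind(names)
            for u, v in edges:
                uf.union(u, v)
            oracle = {}
            for p in names:
                oracle.setdefault(uf.find(p), set()).add(p)
            mine = {frozenset(pid for _, pid in g.members) for g in groups}
            assert mine == {frozenset(s) for s in oracle.values()}


class TestPartition:
    @staticmethod
    def _identical_proteomes(rng, n_strains=10, n_prot=8):
        seqs = [random_protein(rng, 100) for _ in range(n_prot)]
        return [ProteinRecord(f"s{k}", f"s{k}|p{i}", seq)
                for k in range(n_strains) for i, seq in enumerate(seqs)]

    def test_identical_proteomes_all_core(self, rng):
        prots = self._identical_proteomes(rng)
        groups = cluster_single_linkage(prots, similarity_edges(prots))
        meta = {f"s{k}": ("one" if k < 5 else "two") for k in range(10)}
        part = partition_core(groups, meta, ("one", "two"))
        assert part.counts == {"core": 8, "A": 0, "B": 0, "C": 0, "D": 0}

    def test_planted_clade_specific_recovered_exactly(self, rng):
        shared = [random_protein(rng, 100) for _ in range(10)]
        clade1_only = [random_protein(rng, 100) for _ in range(20)]
        prots = []
        for k in range(10):
            strain = f"s{k}"
            for i, seq in enumerate(shared):
                prots.append(ProteinRecord(strain, f"{strain}|c{i}", seq))
            if k < 5:
                for i, seq in enumerate(clade1_only):
                    prots.append(ProteinRecord(strain, f"{strain}|x{i}", seq))
        groups = cluster_single_linkage(prots, similarity_edges(prots))
        meta = {f"s{k}": ("one" if k < 5 else "two") for k in range(10)}
        part = partition_core(groups, meta, ("one", "two"))
        assert part.counts["A"] == 20
        assert part.counts["core"] == 10

    def test_third_label_rejected(self):
        prots = [ProteinRecord("s0", "p", "MKVL")]
        groups = cluster_single_linkage(prots, [])
        with pytest.raises(ValueError, match="two subspecies"):
            partition_core(groups, {"s0": "a", "s1": "b", "s2": "c"})

    def test_partition_invariant_under_input_order(self, dataset, ortholog_groups):
        from conftest import STUDY_LABELS
        proteins, edges, groups = ortholog_groups
        part = partition_core(groups, dataset.meta, STUDY_LABELS)
        rnd = random.Random(0)
        shuffled = proteins[:]
        rnd.shuffle(shuffled)
        edges2 = similarity_edges(shuffled)
        groups2 = cluster_single_linkage(shuffled, edges2)
        part2 = partition_core(groups2, dataset.meta, STUDY_LABELS)
        assert part.counts == part2.counts

    def test_group_conservation_sum_rule(self, dataset, ortholog_groups, core_partition):
        # every group is core, or in B/D, or misses >= 1 strain of both clades
        _, _, groups = ortholog_groups
        part = core_partition
        strains = {lab: {s for s, m in dataset.meta.items() if m == lab}
                   for lab in part.labels}
        rest = 0
        for g in groups:
            missing = {lab: len(strains[lab] - g.strains) for lab in part.labels}
            if all(m >= 1 for m in missing.values()):
                rest += 1
        counted = (part.counts["core"] + part.counts["B"] + part.counts["D"]
                   + part.counts["A"] + part.counts["C"] + rest)
        # A and C are also counted in rest-complement logic: A/C groups miss
        # every strain of one clade and none of the other, so they are
        # disjoint from core, B, D and rest
        assert counted == len(groups)


class TestFragmentRescue:
    def test_no_calls_no_rescue(self):
        from reducto.orthology import OrthologGroup, fragment_rescue
        g = OrthologGroup("OG1", [("s1", "s1|p")])
        n, gids = fragment_rescue([g], [], {"s1": "one", "s2": "two"}, "two")
        assert (n, gids) == (0, [])

    def test_best_hit_membership_drives_rescue(self):
        from reducto.orthology import OrthologGroup, fragment_rescue
        from reducto.pseudogenes import PseudogeneCall
        g = OrthologGroup("OG1", [("s1", "s1|p")])
        call = PseudogeneCall("s2", "s2_frag", "pseudogene_fragment",
                              frozenset({"length_anomaly", "frameshift"}),
                              "s1|p", 0.5)
        other = PseudogeneCall("s2", "s2_other", "pseudogene_fragment",
                               frozenset({"length_anomaly", "internal_stop"}),
                               "s1|unrelated", 0.5)
        meta = {"s1": "one", "s2": "two"}
        n, gids = fragment_rescue([g], [call, other], meta, "two")
        assert (n, gids) == (1, ["OG1"])
        # calls from the home clade never rescue
        n2, _ = fragment_rescue([g], [call], meta, "one")
        assert n2 == 0
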