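"""Alignment, distances, neighbor joining, bootstrap, diagnostic sites and
Robinson-Foulds, with dendropy's tree comparison as the independent check."""

import random

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare
from dendropy.simulate import treesim

from reducto.phylo import (MlstScheme, MultipleAlignment, bipartitions,
                           bootstrap_support, diagnostic_sites,
                           distance_matrix, is_monophyletic, mlst_run,
                           nj_tree, progressive_align, rf_incongruence)


def random_labelled_tree(rnd, n):
    labels = [f"t{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(labels)
    tree = treesim.pure_kingman_tree(taxon_namespace=tns, pop_size=1.0, rng=rnd)
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = rnd.uniform(0.05, 1.0)
    return tree, labels


def path_distance_matrix(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(tns.get_taxon(labels[i]),
                                             tns.get_taxon(labels[j]))
    return d


class TestProgressiveAlign:
    def test_identical_pair_gap_free(self):
        aln = progressive_align({"a": "ACGTACGTAA", "b": "ACGTACGTAA"})
        assert "-" not in "".join(aln.rows)
        assert aln.rows[0] == aln.rows[1]

    def test_single_insertion_makes_one_gap_block(self):
        base = "ATGGCCATTGTAATGGGCCGCTGAAAGGGTGCCCGATAG"
        withins = base[:18] + "CCC" + base[18:]
        aln = progressive_align({"a": base, "b": base, "c": withins})
        for label in ("a", "b"):
            row = aln.row(label)
            assert row.count("-") == 3
            start = row.index("-")
            assert row[start:start + 3] == "---"
            assert "-" not in row[:start] + row[start + 3:]
        assert "-" not in aln.row("c")

    def test_input_order_invariance(self):
        seqs = {"a": "ATGGCCATTGTAATGGGC", "b": "ATGGCCATAGTAATGGGC",
                "c": "ATGGCCATTGTAATGCGC"}
        a1 = progressive_align(seqs)
        a2 = progressive_align(dict(reversed(list(seqs.items()))))
        assert np.allclose(a1.identity_matrix(), a2.identity_matrix())

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            progressive_align({"a": "ACGT"})


class TestDistances:
    def test_identical_rows_zero(self):
        aln = MultipleAlignment(["a", "b"], ["ACGT", "ACGT"])
        assert distance_matrix(aln)[0, 1] == 0.0

    def test_hand_computed_p_distance(self):
        aln = MultipleAlignment(["a", "b"], ["ACGT", "ACGA"])
        assert distance_matrix(aln, "p")[0, 1] == 0.25

    def test_matches_direct_count_oracle(self, rng):
        for _ in range(10):
            n_cols = 60
            rows = ["".join(rng.choice(list("ACGT-"), size=n_cols))
                    for _ in range(2)]
            aln = MultipleAlignment(["a", "b"], rows)
            valid = [(x, y) for x, y in zip(*rows) if "-" not in (x, y)]
            oracle = sum(x != y for x, y in valid) / len(valid)
            assert distance_matrix(aln, "p")[0, 1] == pytest.approx(oracle)

    def test_k2p_undefined_flagged_as_nan(self):
        aln = MultipleAlignment(["a", "b"], ["AAAA", "GGGG"])  # all transitions
        assert np.isnan(distance_matrix(aln, "K2P")[0, 1])

    def test_k2p_matches_closed_form(self):
        aln = MultipleAlignment(["a", "b"], ["AAAACCCC", "GAAACCCA"])
        p, q = 1 / 8, 1 / 8
        expected = -0.5 * np.log((1 - 2 * p - q) * np.sqrt(1 - 2 * q))
        assert distance_matrix(aln, "K2P")[0, 1] == pytest.approx(expected)


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # ((a:1,b:2):1,(c:3,d:4)) as an additive matrix
        labels = ["a", "b", "c", "d"]
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        tree = nj_tree(d, labels)
        assert bipartitions(tree) == {frozenset({"c", "d"})}
        assert np.allclose(path_distance_matrix(tree, labels), d)

    def test_three_taxa_unique_topology(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = nj_tree(d, ["a", "b", "c"])
        assert bipartitions(tree) == set()
        assert np.allclose(path_distance_matrix(tree, ["a", "b", "c"]), d)

    def test_equidistant_matrix_total_length(self):
        n = 5
        d = np.full((n, n), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(d, [f"t{i}" for i in range(n)])
        total = sum(e.length for e in tree.preorder_edge_iter()
                    if e.length is not None)
        # every leaf sits at height 1 from a star-like center
        assert total == pytest.approx(n * 1.0)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d, ["a", "b", "c"])

    def test_additive_recovery_random_trees(self):
        rnd = random.Random(5)
        for _ in range(25):
            tree, labels = random_labelled_tree(rnd, rnd.randint(4, 12))
            d = path_distance_matrix(tree, labels)
            mine = nj_tree(d, labels)
            assert bipartitions(mine) == bipartitions(tree)
            assert np.allclose(path_distance_matrix(mine, labels), d, atol=1e-8)


@pytest.fixture(scope="module")
def two_clade_alignment():
    rng = np.random.default_rng(8)
    base = "".join(rng.choice(list("ACGT"), size=400))

    def mut(seq, k):
        chars = list(seq)
        for pos in rng.choice(len(chars), size=k, replace=False):
            chars[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[chars[pos]]
        return "".join(chars)

    clade1 = mut(base, 80)
    rows = {f"a{i}": mut(clade1, 4) for i in range(3)}
    rows.update({f"b{i}": mut(base, 4) for i in range(3)})
    labels = sorted(rows)
    return MultipleAlignment(labels, [rows[l] for l in labels])


class TestBootstrap:
    def test_separated_clades_get_full_support(self, two_clade_alignment):
        tree = bootstrap_support(two_clade_alignment, n_reps=50, seed=1)
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None or node.label is None:
                continue
            side = {lf.taxon.label for lf in node.leaf_iter()}
            if side in ({"a0", "a1", "a2"}, {"b0", "b1", "b2"}):
                assert float(node.label) == 100.0

    def test_single_replicate_supports_binary(self, two_clade_alignment):
        tree = bootstrap_support(two_clade_alignment, n_reps=1, seed=2)
        vals = {float(n.label) for n in tree.preorder_node_iter()
                if not n.is_leaf() and n.parent_node and n.label}
        assert vals <= {0.0, 100.0}

    def test_fixed_seed_deterministic(self, two_clade_alignment):
        t1 = bootstrap_support(two_clade_alignment, n_reps=20, seed=9)
        t2 = bootstrap_support(two_clade_alignment, n_reps=20, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


class TestDiagnosticSites:
    def _toy(self):
        # groups: g1 (2 rows), g2 (2 rows), g3 (2 rows), query q
        # planted qualifying columns for share={g1,g2} vs differ=g3: 3 of them
        rows = {
            "x1": "AAGGACTTA",
            "x2": "AAGGACTTA",
            "y1": "AAGGTCTTA",
            "y2": "AAGGTCTTA",
            "z1": "CCGGTCATA",
            "z2": "CCGGTCATA",
            "q":  "AAGGACTTA",
        }
        groups = {"x1": "g1", "x2": "g1", "y1": "g2", "y2": "g2",
                  "z1": "g3", "z2": "g3", "q": "query"}
        labels = sorted(rows)
        return MultipleAlignment(labels, [rows[l] for l in labels]), groups

    def test_planted_columns_found(self):
        aln, groups = self._toy()
        sites = diagnostic_sites(aln, groups, {"g1", "g2"}, "g3", query="q")
        # brute-force per-column oracle
        share_rows = ["x1", "x2", "y1", "y2", "q"]
        differ_rows = ["z1", "z2"]
        oracle = []
        for col in range(aln.n_columns):
            sh = {aln.row(l)[col] for l in share_rows}
            df = {aln.row(l)[col] for l in differ_rows}
            if "-" not in sh | df and len(sh) == 1 == len(df) and sh != df:
                oracle.append(col + 1)
        assert sites == oracle
        assert sites == [1, 2, 7]

    def test_all_identical_no_sites(self):
        aln = MultipleAlignment(["a", "b", "c"], ["ACGT"] * 3)
        groups = {"a": "g1", "b": "g1", "c": "g2"}
        assert diagnostic_sites(aln, groups, {"g1"}, "g2") == []

    def test_gap_columns_skipped(self):
        aln = MultipleAlignment(["a", "b"], ["A-G", "C-T"])
        groups = {"a": "g1", "b": "g2"}
        assert diagnostic_sites(aln, groups, {"g1"}, "g2") == [1, 3]

    def test_empty_group_rejected(self):
        aln = MultipleAlignment(["a", "b"], ["AC", "GT"])
        groups = {"a": "g1", "b": "g2"}
        with pytest.raises(ValueError, match="empty"):
            diagnostic_sites(aln, groups, {"g1"}, "g9")


class TestRobinsonFoulds:
    def test_identical_trees(self):
        rnd = random.Random(2)
        tree, labels = random_labelled_tree(rnd, 8)
        other = tree.extract_tree()
        rf, shared, incon = rf_incongruence(tree, other)
        assert rf == 0 and shared == 8 and not incon

    def test_nni_differs_by_two(self):
        t1 = dendropy.Tree.get(data="((a,b),(c,d),e);", schema="newick")
        # one NNI across the internal edge: b swaps with the (c,d) subtree
        t2 = dendropy.Tree.get(data="((a,(c,d)),b,e);", schema="newick")
        rf, shared, incon = rf_incongruence(t1, t2)
        assert shared == 5
        assert rf == 2 and incon
        # enumeration oracle: {c,d} is shared; a|b vs a|(c,d) edges conflict
        assert bipartitions(t1) ^ bipartitions(t2) == {
            frozenset({"c", "d", "e"}), frozenset({"b", "e"})}

    def test_matches_dendropy_oracle(self):
        rnd = random.Random(11)
        for _ in range(15):
            n = rnd.randint(4, 10)
            tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
            t1 = treesim.pure_kingman_tree(taxon_namespace=tns, pop_size=1.0, rng=rnd)
            t2 = treesim.pure_kingman_tree(taxon_namespace=tns, pop_size=1.0, rng=rnd)
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            expected = treecompare.symmetric_difference(t1, t2)
            rf, _, _ = rf_incongruence(t1, t2)
            assert rf == expected

    def test_metric_properties(self):
        rnd = random.Random(13)
        tns = dendropy.TaxonNamespace([f"t{i}" for i in range(7)])
        trees = [treesim.pure_kingman_tree(taxon_namespace=tns, pop_size=1.0,
                                           rng=rnd) for _ in range(4)]
        for a in trees:
            for b in trees:
                rf_ab, _, _ = rf_incongruence(a, b)
                rf_ba, _, _ = rf_incongruence(b, a)
                assert rf_ab == rf_ba >= 0
                assert (rf_ab == 0) == (bipartitions(a) == bipartitions(b))

    def test_disjoint_leaf_sets_rejected(self):
        t1 = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        t2 = dendropy.Tree.get(data="((w,x),(y,z));", schema="newick")
        with pytest.raises(ValueError, match="shared"):
            rf_incongruence(t1, t2)


class TestMlst:
    def test_synthetic_clades_monophyletic(self, dataset):
        from reducto.phylo import extract_mlst_loci
        scheme = MlstScheme(loci=tuple(dataset.scheme),
                            gene_ids=dict(dataset.scheme))
        loci = extract_mlst_loci(dataset.strains, scheme)
        concat, tree = mlst_run(loci, scheme)
        for lab in set(dataset.meta.values()):
            group = {s for s in concat.labels if dataset.meta[s] == lab}
            assert is_monophyletic(tree, group)

    def test_duplicated_strain_zero_length_tree(self):
        seq = "ATGGCCATTGTAATGGGCCGCTGAAAGGGTGCCCGATAG"
        loci = {l: {"s1": seq, "s2": seq} for l in MlstScheme().loci}
        _, tree = mlst_run(loci, MlstScheme())
        total = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
        assert total == 0.0

    def test_strain_missing_locus_excluded(self):
        scheme = MlstScheme()
        seq = "ATGGCCATTGTAATGGGCCGCTGAAAGGGTGCCCGATAG"
        loci = {l: {"s1": seq, "s2": seq, "s3": seq} for l in scheme.loci}
        del loci[scheme.loci[0]]["s3"]
        with pytest.warns(UserWarning, match="s3"):
            concat, _ = mlst_run(loci, scheme)
        assert concat.labels == ["s1", "s2"]
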