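"""Tree machinery: alignment handling, distances, neighbor joining,
rooting, monophyly, tree splitting and topology comparison."""

import math

import dendropy
import numpy as np
import pytest

from orthosift import phylo
from orthosift.phylo import GeneTree, Node

from conftest import make_records, random_protein


def random_topology(rng, names):
    """Random rooted binary tree with random branch lengths."""
    nodes = [Node(name=n, length=float(rng.uniform(0.05, 1.0))) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=float(rng.uniform(0.05, 1.0)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = 0.0
    return GeneTree(root)


def path_distances(tree):
    leaves = tree.leaves()
    names = [l.name for l in leaves]
    n = len(leaves)
    d = np.zeros((n, n))

    def ancestors(x):
        out = []
        while x is not None:
            out.append(x)
            x = x.parent
        return out

    for i in range(n):
        pa = ancestors(leaves[i])
        ids = {id(x): k for k, x in enumerate(pa)}
        for j in range(i + 1, n):
            x, db = leaves[j], 0.0
            while id(x) not in ids:
                db += x.length
                x = x.parent
            da = sum(a.length for a in pa[: ids[id(x)]])
            d[i, j] = d[j, i] = da + db
    return d, names


class TestAlignCandidate:
    def test_equal_length_pass_through(self, rng):
        recs = make_records({f"sp{i}": [random_protein(rng, 200)]
                             for i in range(1, 4)})
        aln = phylo.align_candidate(recs)
        assert aln.n_sites == 200
        assert aln.rows == {r.seq_id: r.protein for r in recs}

    def test_identical_pair_aligns_without_gaps(self):
        s = "MKVLATPWGQR" * 4
        recs = make_records({"sp1": [s], "sp2": [s]})
        aln = phylo.align_candidate(recs)
        assert set(aln.rows.values()) == {s}

    def test_membership_permutation_invariance(self, rng):
        seqs = {f"sp{i}": [random_protein(rng, 150)] for i in range(1, 5)}
        recs = make_records(seqs)
        a = phylo.align_candidate(recs)
        b = phylo.align_candidate(list(reversed(recs)))
        assert a.rows == b.rows

    def test_builtin_progressive_on_unequal_lengths(self, rng):
        core = random_protein(rng, 60)
        recs = make_records({"sp1": [core], "sp2": [core[:20] + core[25:]],
                             "sp3": [core + "WWL"]})
        aln = phylo.align_candidate(recs)
        lengths = {len(r) for r in aln.rows.values()}
        assert len(lengths) == 1
        # degapped rows reproduce the inputs
        originals = {r.seq_id: r.protein for r in recs}
        assert {k: v.replace("-", "") for k, v in aln.rows.items()} == originals

    def test_mafft_adapter(self, rng):
        core = random_protein(rng, 80)
        recs = make_records({"sp1": [core], "sp2": [core[:30] + core[36:]]})
        aln = phylo.align_candidate(recs, aligner=phylo.mafft_aligner)
        assert len({len(r) for r in aln.rows.values()}) == 1


class TestTrimAlignment:
    def test_single_gap_removes_one_column(self):
        aln = phylo.Alignment(rows={"a": "MKVLAYTPW", "b": "MKVLA-TPW"})
        trimmed = phylo.trim_alignment(aln)
        assert trimmed.n_sites == 8

    def test_gapless_input_is_fixed_point_and_idempotent(self, rng):
        aln = phylo.Alignment(rows={f"s{i}": random_protein(rng, 50)
                                    for i in range(4)})
        once = phylo.trim_alignment(aln)
        assert once.rows == aln.rows
        gappy = phylo.Alignment(rows={"a": "MK-LA", "b": "MKV-A", "c": "MKVLA"})
        once = phylo.trim_alignment(gappy)
        assert phylo.trim_alignment(once).rows == once.rows

    def test_all_columns_gapped_is_an_error(self):
        aln = phylo.Alignment(rows={"a": "M-", "b": "-K"})
        with pytest.raises(ValueError, match="empty after trimming"):
            phylo.trim_alignment(aln)


class TestDistanceMatrix:
    def test_identical_rows_zero_distance(self):
        aln = phylo.Alignment(rows={"a": "MKVLA" * 10, "b": "MKVLA" * 10})
        d, names = phylo.distance_matrix(aln)
        assert d[0, 1] == 0.0

    def test_poisson_correction_closed_form(self, rng):
        row = random_protein(rng, 200)
        other = list(row)
        for pos in range(0, 200, 10):  # exactly 20 mismatches: p = 0.1
            other[pos] = "W" if row[pos] != "W" else "Y"
        d, _ = phylo.distance_matrix(
            phylo.Alignment(rows={"a": row, "b": "".join(other)}))
        assert d[0, 1] == pytest.approx(-math.log(0.9), abs=1e-9)

    def test_symmetry_zero_diagonal_and_saturation_clamp(self, rng):
        aln = phylo.Alignment(rows={"a": "A" * 100, "b": "W" * 100,
                                    "c": random_protein(rng, 100)})
        d, _ = phylo.distance_matrix(aln)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        assert d[0, 1] == pytest.approx(-math.log(0.05))

    def test_zero_comparable_sites_is_an_error(self):
        aln = phylo.Alignment(rows={"a": "MK--", "b": "--VL"})
        with pytest.raises(ValueError, match="no mutually ungapped"):
            phylo.distance_matrix(aln)


class TestNeighborJoining:
    @pytest.mark.parametrize("n_leaves", [8, 13, 21])
    def test_additive_matrix_recovery(self, rng, n_leaves):
        t = random_topology(rng, [f"t{i:02d}" for i in range(n_leaves)])
        d, names = path_distances(t)
        nj = phylo.nj_tree(d, names)
        assert phylo.rf_distance(nj, t) == 0
        d2, names2 = path_distances(nj)
        idx = [names2.index(x) for x in names]
        assert np.abs(d2[np.ix_(idx, idx)] - d).max() < 1e-9

    def test_three_taxa_unique_topology(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        t = phylo.nj_tree(d, ["a", "b", "c"])
        assert len(t.root.children) == 3
        assert t.leaf_names() == ["a", "b", "c"]

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            phylo.nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_leaf_order_permutation_invariance(self, rng):
        t = random_topology(rng, [f"t{i}" for i in range(10)])
        d, names = path_distances(t)
        perm = rng.permutation(len(names))
        nj1 = phylo.nj_tree(d, names)
        nj2 = phylo.nj_tree(d[np.ix_(perm, perm)], [names[i] for i in perm])
        assert phylo.rf_distance(nj1, nj2) == 0

    def test_agrees_with_independent_implementation(self, rng):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        t = random_topology(rng, [f"t{i}" for i in range(9)])
        d, names = path_distances(t)
        ours = phylo.nj_tree(d, names)
        theirs = skbio_nj(DistanceMatrix(d, ids=names))
        theirs_gt = phylo.from_newick(str(theirs.root()).strip())
        assert phylo.rf_distance(ours, theirs_gt) == 0


class TestRootBetweenGroups:
    def test_clean_split_gives_pure_root_clades(self):
        t = phylo.from_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        group_of = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        r = phylo.root_between_groups(t, group_of)
        sides = [sorted(l.name for l in GeneTree(c).leaves())
                 for c in r.root.children]
        assert sorted(sides) == [["a1", "a2"], ["b1", "b2"]]

    def test_single_group_is_an_error(self):
        t = phylo.from_newick("((a1:1,a2:1):1,a3:1);")
        with pytest.raises(ValueError, match="one group absent"):
            phylo.root_between_groups(t, {"a1": "A", "a2": "A", "a3": "A"})

    def test_mixed_tree_roots_deterministically(self, rng):
        names = [f"x{i}" for i in range(10)]
        t = random_topology(rng, names)
        group_of = {n: ("A" if i % 3 else "B") for i, n in enumerate(names)}
        r1 = phylo.root_between_groups(t, group_of)
        r2 = phylo.root_between_groups(t, group_of)
        assert phylo.to_newick(r1) == phylo.to_newick(r2)

    def test_tie_broken_by_longer_branch(self):
        # interleaved groups: every leaf edge misplaces exactly one leaf,
        # so the longest of the tied edges (b1) must carry the root
        t = phylo.from_newick("((a1:1,b1:2):1,(a2:1,b2:1):1);")
        group_of = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        r = phylo.root_between_groups(t, group_of)
        sides = [sorted(l.name for l in GeneTree(c).leaves())
                 for c in r.root.children]
        assert ["b1"] in sides


class TestClassifyMonophyly:
    def test_clean_and_interleaved_group_trees(self):
        group_of = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        mono = phylo.from_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        poly = phylo.from_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        assert phylo.classify_monophyly(mono, group_of) == "monophyletic"
        assert phylo.classify_monophyly(poly, group_of) == "polyphyletic"

    def test_singleton_labels_are_trivial_clades(self):
        t = phylo.from_newick("((a1:1,b1:1):1,c1:1);")
        labels = {"a1": "A", "b1": "B", "c1": "A"}
        # A has two leaves split across the tree -> polyphyletic
        assert phylo.classify_monophyly(t, labels) == "polyphyletic"
        labels2 = {"a1": "A", "b1": "B", "c1": "C"}
        assert phylo.classify_monophyly(t, labels2) == "monophyletic"

    @pytest.mark.parametrize("trial", range(20))
    def test_agrees_with_dendropy_mrca_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 11))
        names = [f"x{i}" for i in range(n)]
        t = random_topology(rng, names)
        labels = {nm: f"L{int(rng.integers(3))}" for nm in names}
        dt = dendropy.Tree.get(data=phylo.to_newick(t), schema="newick",
                               preserve_underscores=True)
        dt.is_rooted = True
        expected = "monophyletic"
        for lab in set(labels.values()):
            taxa = [nm for nm in names if labels[nm] == lab]
            if len(taxa) < 2:
                continue
            mrca = dt.mrca(taxon_labels=taxa)
            clade = {l.taxon.label for l in mrca.leaf_iter()}
            if clade != set(taxa):
                expected = "polyphyletic"
        assert phylo.classify_monophyly(t, labels) == expected


class TestSplitTree:
    GROUPS = {f"s{i}": ("G1" if i <= 8 else "G2") for i in range(1, 11)}

    def _post_duplication_tree(self):
        """Gene tree after whole-family duplication with complementary
        losses: the alpha copy keeps species 1-3 and 9-10, the beta copy
        keeps 4-5 only; the branch at the duplication point is longest."""
        alpha = "(((s1_a:0.04,s2_a:0.04):0.04,s3_a:0.04):0.04,(s9_a:0.04,s10_a:0.04):0.04)"
        beta = "(s4_b:0.04,s5_b:0.04)"
        return phylo.from_newick(f"({alpha}:0.10,{beta}:0.10);")

    def test_duplication_point_cut_retains_consistent_component(self):
        t = self._post_duplication_tree()
        species_of = {l.name: l.name.split("_")[0] for l in t.leaves()}
        group_of = {l.name: self.GROUPS[species_of[l.name]] for l in t.leaves()}
        assert phylo.classify_monophyly(t, group_of) == "polyphyletic"
        res = phylo.split_tree(t, group_of, group_of, species_of,
                               min_species_per_group=2)
        assert res.success
        kept = set(res.tree.leaf_names())
        assert kept == {"s1_a", "s2_a", "s3_a", "s9_a", "s10_a"}
        assert phylo.classify_monophyly(
            res.tree, {k: group_of[k] for k in kept}) == "monophyletic"

    def test_exhaustion_restores_original(self):
        # every cut leaves some component without 2 species per group
        t = phylo.from_newick("((s1_x:1,s9_x:1):1,(s2_x:1,s10_x:1):1);")
        species_of = {l.name: l.name.split("_")[0] for l in t.leaves()}
        group_of = {l.name: self.GROUPS[species_of[l.name]] for l in t.leaves()}
        before = phylo.to_newick(t)
        res = phylo.split_tree(t, group_of, group_of, species_of,
                               min_species_per_group=2)
        assert not res.success
        assert phylo.to_newick(res.tree) == before

    def test_species_level_split_removes_stray_paralog(self):
        # s1 contributes two genes in conflicting positions; cutting the
        # stray leaf yields a one-gene-per-species remainder
        t = phylo.from_newick(
            "(((s1_p:0.9,s2_g:0.04):0.04,(s1_g:0.04,s3_g:0.04):0.04):0.1,"
            "(s9_g:0.04,s10_g:0.04):0.1);")
        species_of = {l.name: l.name.split("_")[0] for l in t.leaves()}
        group_of = {l.name: self.GROUPS[species_of[l.name]] for l in t.leaves()}
        sp_labels = dict(species_of)
        assert phylo.classify_monophyly(t, sp_labels) == "polyphyletic"
        res = phylo.split_tree(t, sp_labels, group_of, species_of,
                               min_species_per_group=2)
        assert res.success
        kept = set(res.tree.leaf_names())
        assert kept == {"s1_g", "s2_g", "s3_g", "s9_g", "s10_g"}
        assert phylo.classify_monophyly(
            res.tree, {k: sp_labels[k] for k in kept}) == "monophyletic"


class TestSameTopology:
    def test_branch_lengths_ignored(self, rng):
        t = random_topology(rng, [f"x{i}" for i in range(8)])
        t2 = t.copy()
        for n in t2.nodes():
            n.length *= 3.0
        assert phylo.same_topology(t, t2)
        assert phylo.same_topology(t2, t)

    def test_single_nni_move_detected(self):
        t1 = phylo.from_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        t2 = phylo.from_newick("((a:1,c:1):1,(b:1,d:1):1,e:1);")
        assert not phylo.same_topology(t1, t2)

    def test_leaf_set_mismatch_is_an_error(self):
        t1 = phylo.from_newick("((a:1,b:1):1,c:1);")
        t2 = phylo.from_newick("((a:1,b:1):1,d:1);")
        with pytest.raises(ValueError):
            phylo.same_topology(t1, t2)


class TestRestrictToLeaves:
    def test_prune_preserves_path_lengths(self, rng):
        t = random_topology(rng, [f"x{i}" for i in range(12)])
        keep = [f"x{i}" for i in range(0, 12, 2)]
        sub = phylo.restrict_to_leaves(t, keep)
        assert sub.leaf_names() == sorted(keep)
        d_full, names_full = path_distances(t)
        d_sub, names_sub = path_distances(sub)
        for i, a in enumerate(names_sub):
            for j, b in enumerate(names_sub):
                fi, fj = names_full.index(a), names_full.index(b)
                assert d_sub[i, j] == pytest.approx(d_full[fi, fj], abs=1e-9)
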