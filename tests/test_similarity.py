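"""S_G similarity, guide tree construction, Newick output, sequence order."""

import math

import dendropy
import numpy as np
import pytest

from syntelign import AlignParams, Hsp, SeqRecord, all_pairs, validate_input_set
from syntelign.fixtures import make_related_set, make_two_cluster_set, random_sequence
from syntelign.similarity import (
    SimilarityMatrix,
    build_guide_tree,
    compute_sg,
    order_sequences,
    pair_score,
    write_newick,
)


def _hsp(qs, qe, ss, se, bits):
    return Hsp(
        query_id="a", subject_id="b", qstart=qs, qend=qe, sstart=ss, send=se,
        subject_reversed=False, identity_pct=90.0, raw_score=bits,
        bit_score=bits, evalue=1e-10,
    )


class TestPairScore:
    def test_empty_list_scores_zero(self):
        assert pair_score([]) == 0.0

    def test_single_hsp_is_identity(self):
        assert pair_score([_hsp(0, 200, 0, 200, 200.0)]) == 200.0

    def test_greedy_nonredundant_selection(self):
        """Disjoint 200+100 bits kept; a fully overlapping 150 skipped."""
        hsps = [
            _hsp(0, 1000, 0, 1000, 200.0),
            _hsp(2000, 2500, 2000, 2500, 100.0),
            _hsp(0, 900, 0, 900, 150.0),  # > 50% overlap with the first
        ]
        assert pair_score(hsps) == 300.0


class TestComputeSg:
    def test_identical_pair_scores_one(self, nt_params):
        recs, _ = make_related_set(2, 4000, 1.0, seed=1)
        inp = validate_input_set(recs)
        sim = compute_sg(all_pairs(inp, nt_params), inp)
        assert sim.value("s1", "s2") == 1.0

    def test_unrelated_pair_scores_zero(self, nt_params, rng):
        a = SeqRecord(id="a", sequence=random_sequence(4000, rng))
        b = SeqRecord(id="b", sequence=random_sequence(4000, rng))
        inp = validate_input_set([a, b])
        sim = compute_sg(all_pairs(inp, nt_params), inp)
        assert sim.value("a", "b") == 0.0

    def test_half_copy_scales_as_sqrt_length_ratio(self, nt_params, rng):
        """b = first half of a: S_G ~ sqrt(|b|/|a|) up to edge effects."""
        s = random_sequence(2000, rng)
        a = SeqRecord(id="a", sequence=s)
        b = SeqRecord(id="b", sequence=s[:1000])
        inp = validate_input_set([a, b])
        sim = compute_sg(all_pairs(inp, nt_params), inp)
        assert sim.value("a", "b") == pytest.approx(math.sqrt(0.5), rel=0.02)

    def test_bounds_symmetry_unit_diagonal(self, nt_params):
        recs, _ = make_related_set(4, 2000, 0.85, seed=3)
        inp = validate_input_set(recs)
        sim = compute_sg(all_pairs(inp, nt_params), inp)
        assert np.allclose(sim.sg, sim.sg.T)
        assert np.all(np.diag(sim.sg) == 1.0)
        assert np.all((sim.sg >= 0.0) & (sim.sg <= 1.0))

    def test_mutation_ladder_monotone(self, nt_params):
        """More mutations never increase S_G (one adjacent inversion allowed)."""
        values = []
        for ident in (1.0, 0.95, 0.9, 0.85, 0.8, 0.75):
            recs, _ = make_related_set(2, 3000, ident, seed=4)
            inp = validate_input_set(recs)
            sim = compute_sg(all_pairs(inp, nt_params), inp)
            values.append(sim.value("s1", "s2"))
        violations = sum(1 for x, y in zip(values, values[1:]) if y > x + 1e-12)
        assert violations <= 1, values

    def test_zero_self_score_is_hard_error(self, nt_params):
        a = SeqRecord(id="badseq", sequence="N" * 1000)
        b = SeqRecord(id="b", sequence="ACGT" * 250)
        inp = validate_input_set([a, b])
        hits = all_pairs(inp, nt_params)
        with pytest.raises(ValueError, match="badseq"):
            compute_sg(hits, inp)


class TestGuideTree:
    def test_closest_pair_grouped(self):
        sim = SimilarityMatrix(
            ids=["a", "b", "c"],
            sg=np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]]),
        )
        tree = build_guide_tree(sim)
        order = tree.leaf_order
        assert abs(order.index("a") - order.index("b")) == 1

    def test_no_tree_for_two_sequences(self):
        sim = SimilarityMatrix(ids=["a", "b"], sg=np.eye(2))
        with pytest.raises(ValueError, match="fewer than three"):
            build_guide_tree(sim)

    def test_planted_clusters_contiguous(self, nt_params):
        recs, clusters = make_two_cluster_set(seed=8)
        inp = validate_input_set(recs)
        sim = compute_sg(all_pairs(inp, nt_params), inp)
        order = build_guide_tree(sim).leaf_order
        for pair in clusters:
            i, j = sorted(order.index(x) for x in pair)
            assert j - i == 1, order

    def test_matches_scipy_average_linkage(self):
        """Cross-check topology against scipy's UPGMA on a tie-free matrix."""
        from scipy.cluster.hierarchy import average, leaves_list
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(5)
        n = 6
        m = rng.random((n, n)) * 0.8
        sg = (m + m.T) / 2
        np.fill_diagonal(sg, 1.0)
        ids = [f"g{i}" for i in range(n)]
        sim = SimilarityMatrix(ids=ids, sg=sg)
        tree = build_guide_tree(sim)

        Z = average(squareform(1.0 - sg, checks=False))
        # compare the sets of leaf bipartitions (clusters) rather than order
        def clusters_from_tree(node, acc):
            ls = frozenset(node.leaves())
            if len(ls) > 1:
                acc.add(ls)
                for c in node.children:
                    clusters_from_tree(c, acc)
            return acc

        ours = clusters_from_tree(tree.root, set())
        members = {i: frozenset([ids[i]]) for i in range(n)}
        scipy_clusters = set()
        for k, (i, j, _, _) in enumerate(Z):
            merged = members[int(i)] | members[int(j)]
            members[n + k] = merged
            scipy_clusters.add(merged)
        assert ours == scipy_clusters

    def test_deterministic_under_ties(self):
        sg = np.full((4, 4), 0.5)
        np.fill_diagonal(sg, 1.0)
        sim = SimilarityMatrix(ids=["d", "c", "b", "a"], sg=sg)
        t1 = build_guide_tree(sim)
        t2 = build_guide_tree(sim)
        assert t1.leaf_order == t2.leaf_order
        assert write_newick(t1) == write_newick(t2)


class TestNewick:
    def test_roundtrip_topology(self):
        sim = SimilarityMatrix(
            ids=["a", "b", "c"],
            sg=np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]]),
        )
        tree = build_guide_tree(sim)
        nwk = write_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick",
                                   rooting="force-rooted")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == [
            "a", "b", "c"
        ]
        # a and b form the cherry
        mrca = parsed.mrca(taxon_labels=["a", "b"])
        assert len(mrca.leaf_nodes()) == 2

    def test_branch_lengths_nonnegative_and_ultrametric(self):
        rng = np.random.default_rng(9)
        n = 5
        m = rng.random((n, n)) * 0.9
        sg = (m + m.T) / 2
        np.fill_diagonal(sg, 1.0)
        sim = SimilarityMatrix(ids=[f"t{i}" for i in range(n)], sg=sg)
        nwk = write_newick(build_guide_tree(sim))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        depths = []
        for leaf in tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                assert node.edge.length >= 0
                d += node.edge.length
                node = node.parent_node
            depths.append(d)
        # branch lengths are printed to 6 significant digits
        assert max(depths) - min(depths) < 1e-5

    def test_spaces_in_labels_escaped(self):
        sg = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
        sim = SimilarityMatrix(ids=["seq one", "seq two", "c"], sg=sg)
        nwk = write_newick(build_guide_tree(sim))
        assert "seq_one" in nwk and " " not in nwk


class TestOrderSequences:
    def test_two_sequences_keep_input_order(self, nt_params):
        recs, _ = make_related_set(2, 1500, 0.9, seed=10)
        inp = validate_input_set(recs)
        assert order_sequences(inp, None) == ["s1", "s2"]

    def test_tree_order_is_permutation(self, nt_params):
        recs, _ = make_related_set(4, 1500, 0.85, seed=11)
        inp = validate_input_set(recs)
        sim = compute_sg(all_pairs(inp, nt_params), inp)
        order = order_sequences(inp, build_guide_tree(sim))
        assert sorted(order) == sorted(inp.ids)
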