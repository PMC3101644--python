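"""Simulator: model trees, gene gain/loss, sequence evolution, estimation."""

import numpy as np
import pytest

from supertreesim import profile_sim as ps
from supertreesim.treekit import bipartition_set, read_newick, restrict, same_topology


class TestModelTree:
    def test_leaf_count_and_rootedness(self):
        t = ps.simulate_model_tree(10, seed=1)
        assert t.n_leaves == 10
        internal = [
            nd for nd in t.dendropy_tree.preorder_node_iter() if not nd.is_leaf()
        ]
        assert len(internal) == 9  # rooted binary

    def test_zero_deviation_is_ultrametric(self):
        t = ps.simulate_model_tree(12, deviation_sd=0.0, seed=3)
        depths = [lf.distance_from_root() for lf in t.dendropy_tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_seed_determinism_and_variety(self):
        a = ps.simulate_model_tree(10, seed=5).to_newick()
        b = ps.simulate_model_tree(10, seed=5).to_newick()
        assert a == b
        topologies = {
            frozenset(bipartition_set(ps.simulate_model_tree(10, seed=s)))
            for s in range(20)
        }
        assert len(topologies) > 1

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            ps.simulate_model_tree(3)


class TestGeneLeafsets:
    def test_root_gain_no_loss_covers_everything(self):
        t = ps.simulate_model_tree(16, seed=2)
        sets = ps.assign_gene_leafsets(
            t, 5, loss_rate=0.0, gain_at_root=True, seed=0
        )
        assert all(s == t.leaves for s in sets)

    def test_leafsets_are_clades_minus_clades(self):
        """A gene leaf set must be the leaves below some node minus leaf
        sets of complete subtrees: every maximal missing subtree below the
        gain point is missing entirely."""
        t = ps.simulate_model_tree(20, seed=4)
        dt = t.dendropy_tree
        for gene in ps.assign_gene_leafsets(t, 30, seed=7):
            # gain node: smallest clade containing the gene
            candidates = [
                nd
                for nd in dt.postorder_node_iter()
                if gene <= {lf.taxon.label for lf in nd.leaf_iter()}
            ]
            gain = min(
                candidates, key=lambda nd: len(nd.leaf_nodes())
            )

            def check(node):
                leaves = {lf.taxon.label for lf in node.leaf_iter()}
                if not (leaves & gene):
                    return  # whole subtree lost: fine
                if leaves <= gene:
                    return  # whole subtree present: fine
                assert not node.is_leaf()
                for ch in node.child_nodes():
                    check(ch)

            check(gain)

    def test_gain_share_matches_edge_length_share(self):
        """With no loss, the fraction of genes whose leaf set equals a
        clade's leaves estimates that clade edge's share of total gain
        weight (binomial sampling oracle, 3 standard errors)."""
        t = ps.simulate_model_tree(10, seed=11)
        dt = t.dendropy_tree
        lengths = [
            e.length for e in dt.preorder_edge_iter() if e.tail_node is not None
        ]
        stem = sum(lengths) / 2.0
        total = sum(lengths) + stem
        # pick the internal edge with the largest clade below it
        node = max(
            (
                nd
                for nd in dt.preorder_node_iter()
                if nd.parent_node is not None
                and not nd.is_leaf()
                and 4 <= len(nd.leaf_nodes()) < 10
            ),
            key=lambda nd: nd.edge.length,
        )
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        p = node.edge.length / total
        genes = ps.assign_gene_leafsets(t, 1000, loss_rate=0.0, min_leaves=1, seed=5)
        hits = sum(g == clade for g in genes)
        se = np.sqrt(1000 * p * (1 - p))
        assert abs(hits - 1000 * p) <= 3 * se

    def test_unsatisfiable_minimum(self):
        t = ps.simulate_model_tree(6, seed=0)
        with pytest.raises(ValueError):
            ps.assign_gene_leafsets(t, 1, min_leaves=7)


class TestEvolveSequences:
    def test_zero_lengths_give_identical_sequences(self):
        t = read_newick("((a:0,b:0):0,(c:0,d:0):0);")
        aln = ps.evolve_sequences(t, ps.GTRModel.preset("jc"), 80, seed=1)
        assert len({row.tobytes() for row in aln.data}) == 1

    def test_invariable_sites_mostly_constant(self):
        t = read_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        model = ps.GTRModel(alpha=50.0, p_inv=0.99)
        aln = ps.evolve_sequences(t, model, 10000, seed=2)
        constant = (aln.data == aln.data[0]).all(axis=0).mean()
        assert constant >= 0.95

    def test_long_branch_reaches_stationarity(self):
        t = read_newick("(a:0,b:8);")
        model = ps.GTRModel.preset("default")
        aln = ps.evolve_sequences(t, model, 100000, seed=3)
        b = aln.data[aln.taxa.index("b")]
        freqs = np.bincount(b, minlength=4) / len(b)
        assert np.abs(freqs - np.array(model.freqs)).max() < 0.01

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            ps.GTRModel(freqs=(0.5, 0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            ps.GTRModel(alpha=0.0)
        with pytest.raises(ValueError):
            ps.GTRModel.preset("unknown-preset")

    def test_rate_matrix_normalized(self):
        m = ps.GTRModel.preset("default")
        Q = m.rate_matrix()
        pi = np.array(m.freqs)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)
        assert (pi @ Q) == pytest.approx(np.zeros(4), abs=1e-12)


class TestAssembleDatasets:
    def test_scaffold_size_and_uniqueness(self):
        t = ps.simulate_model_tree(20, seed=1)
        cond = ps.ModelCondition(n=20, scaffold_density=0.5, loss_rate=0.0)
        datasets = ps.assemble_datasets(t, cond, seed=2)
        scaffolds = [d for d in datasets if d.tag == "scaffold"]
        assert len(scaffolds) == 1  # mixed: exactly one scaffold
        assert len(scaffolds[0].taxa) == 10  # round(p * n), no loss

    def test_clade_datasets_are_clades(self):
        t = ps.simulate_model_tree(24, seed=3)
        clades = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter())
            for nd in t.dendropy_tree.preorder_node_iter()
            if not nd.is_leaf()
        }
        cond = ps.ModelCondition(n=24, scaffold_density=0.5, loss_rate=0.0)
        for ds in ps.assemble_datasets(t, cond, seed=4):
            if ds.tag == "clade":
                assert ds.taxa in clades

    def test_all_scaffold_profiles(self):
        t = ps.simulate_model_tree(16, seed=5)
        cond = ps.ModelCondition(
            n=16, scaffold_density=0.5, profile_type="all-scaffold"
        )
        datasets = ps.assemble_datasets(t, cond, seed=6)
        assert all(d.tag == "scaffold" for d in datasets)
        assert len(datasets) == cond.n_datasets

    def test_tiny_scaffold_rejected(self):
        t = ps.simulate_model_tree(12, seed=7)
        cond = ps.ModelCondition(n=12, scaffold_density=0.25)
        with pytest.raises(ValueError, match="scaffold"):
            ps.assemble_datasets(t, cond, seed=0)


class TestEstimation:
    def test_nj_recovers_additive_metric(self):
        # hand-built additive metric on the 6-leaf three-cherry tree
        tree = read_newick("((a:1,b:2):1,(c:1,d:1):2,(e:3,f:1):1);")
        from supertreesim.treekit import weighted_dist_matrix

        labels, D = weighted_dist_matrix(tree)
        est = ps.nj_tree(D, labels)
        assert bipartition_set(est) == bipartition_set(tree)

    def test_jc_correction_values(self):
        aln = ps.Alignment(
            ["a", "b"],
            np.array([[0] * 90 + [1] * 10, [0] * 100], dtype=np.int8),
        )
        D = ps.corrected_distance_matrix(aln)
        expected = -0.75 * np.log(1 - 4 * 0.1 / 3)
        assert D[0, 1] == pytest.approx(expected)

    def test_saturated_pair_falls_back(self, caplog):
        aln = ps.Alignment(
            ["a", "b"], np.array([[0] * 10, [1] * 10], dtype=np.int8)
        )
        with caplog.at_level("WARNING"):
            D = ps.corrected_distance_matrix(aln)
        assert D[0, 1] == pytest.approx(1.0)  # uncorrected fraction
        assert any("saturated" in r.message for r in caplog.records)

    def test_disjoint_pair_imputed_via_intermediate(self):
        # a/b share no sites but both overlap c; their distance must be
        # imputed through c rather than invented
        a = [0] * 50 + [-1] * 50
        b = [-1] * 50 + [0] * 50
        c = [0] * 100
        aln = ps.Alignment(["a", "b", "c"], np.array([a, b, c], dtype=np.int8))
        D = ps.corrected_distance_matrix(aln)
        assert D[0, 1] == pytest.approx(D[0, 2] + D[1, 2])

    def test_estimator_statistical_consistency(self):
        """Long alignments on an 8-taxon tree: correct topology in >= 8
        of 10 seeds."""
        t = read_newick(
            "(((a:0.2,b:0.15):0.08,(c:0.1,d:0.25):0.06):0.05,"
            "((e:0.3,f:0.12):0.07,(g:0.18,h:0.22):0.09):0.05);"
        )
        hits = 0
        for seed in range(10):
            aln = ps.evolve_sequences(t, ps.GTRModel.preset("jc"), 5000, seed=seed)
            ds = ps.Dataset("x", "scaffold", t.leaves, [aln])
            est = ps.estimate_source_tree(ds)
            hits += bipartition_set(est) == bipartition_set(t)
        assert hits >= 8

    def test_output_leafset_and_small_dataset_error(self):
        t = ps.simulate_model_tree(8, seed=1)
        aln = ps.evolve_sequences(t, ps.GTRModel.preset("jc"), 100, seed=1)
        ds = ps.Dataset("x", "clade", t.leaves, [aln])
        assert ps.estimate_source_tree(ds).leaves == t.leaves
        tiny = ps.Dataset("y", "clade", frozenset("abc"), [])
        with pytest.raises(ValueError):
            ps.estimate_source_tree(tiny)


class TestBuildProfile:
    def test_deterministic_manifest(self):
        cond = ps.ModelCondition(n=12, scaffold_density=0.5, sites_per_gene=100,
                                 clade_size_min=4)
        m1, p1 = ps.build_profile(cond, seed=9)
        m2, p2 = ps.build_profile(cond, seed=9)
        assert p1.manifest == p2.manifest
        assert m1.to_newick() == m2.to_newick()
        assert [t.tree.to_newick() for t in p1] == [t.tree.to_newick() for t in p2]

    def test_source_taxa_within_model_tree(self):
        cond = ps.ModelCondition(n=16, scaffold_density=0.5, sites_per_gene=100)
        mt, prof = ps.build_profile(cond, seed=2)
        for st in prof:
            assert st.taxa <= mt.leaves
            assert st.m_t == len(bipartition_set(st.tree))

    def test_true_source_tree_mode_is_error_free(self):
        cond = ps.ModelCondition(n=16, scaffold_density=1.0, estimator="true",
                                 sites_per_gene=50)
        mt, prof = ps.build_profile(cond, seed=3)
        for st in prof:
            truth = restrict(mt, st.taxa)
            assert bipartition_set(st.tree) == bipartition_set(truth)

    def test_profile_dir_roundtrip(self, tmp_path):
        cond = ps.ModelCondition(n=12, scaffold_density=0.5, sites_per_gene=50,
                                 clade_size_min=4)
        mt, prof = ps.build_profile(cond, seed=4)
        ps.write_profile_dir(tmp_path / "rep", mt, prof)
        again = ps.read_profile_dir(tmp_path / "rep")
        assert same_topology(again.model_tree, mt)
        assert len(again) == len(prof)
        assert [t.tag for t in again] == [t.tag for t in prof]
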