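"""Ward clustering of predicted genetic-value vectors and Newick output."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regionpred.cluster import (
    Dendrogram,
    gvalue_distance_matrix,
    ward_cluster,
    ward_cluster_bruteforce,
    write_newick,
)


class TestDistanceMatrix:
    def test_identical_and_pythagorean_distances(self):
        names, D = gvalue_distance_matrix({
            "r": np.array([0.0, 0.0]),
            "s": np.array([3.0, 4.0]),
            "t": np.array([0.0, 0.0]),
        })
        i, j, k = names.index("r"), names.index("s"), names.index("t")
        assert D[i, j] == pytest.approx(5.0)
        assert D[i, k] == 0.0
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)

    def test_hand_worked_four_regions(self):
        rng = np.random.default_rng(1)
        vecs = {f"R{k}": rng.normal(size=6) for k in range(4)}
        names, D = gvalue_distance_matrix(vecs)
        for a in range(4):
            for b in range(4):
                expected = np.sqrt(((vecs[names[a]] - vecs[names[b]]) ** 2).sum())
                assert D[a, b] == pytest.approx(expected)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            gvalue_distance_matrix({"a": np.zeros(3), "b": np.zeros(4)})


class TestWard:
    def test_two_leaves_single_merge_at_sse_height(self):
        D = np.array([[0.0, 4.0], [4.0, 0.0]])
        d = ward_cluster(D, labels=["A", "B"])
        assert len(d.merges) == 1
        # SSE increase of merging two points at distance 4 is 16/2 = 8
        assert d.merges[0][2] == pytest.approx(8.0)

    def test_well_separated_pairs_merge_first(self):
        pts = {"p0": np.array([0.0]), "p1": np.array([1.0]),
               "p2": np.array([10.0]), "p3": np.array([11.0])}
        names, D = gvalue_distance_matrix(pts)
        d = ward_cluster(D, labels=names)
        first_two = {frozenset(m[:2]) for m in d.merges[:2]}
        assert frozenset(("p0", "p1")) in first_two
        assert frozenset(("p2", "p3")) in first_two

    def test_matches_bruteforce_sse_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            vecs = {f"L{k}": rng.normal(size=4) for k in range(5)}
            names, D = gvalue_distance_matrix(vecs)
            fast = ward_cluster(D, labels=names)
            slow = ward_cluster_bruteforce(vecs)
            assert [m[:2] for m in fast.merges] == [m[:2] for m in slow.merges]
            assert np.allclose(fast.heights(), slow.heights())

    def test_agrees_with_scipy_linkage_heights(self):
        from scipy.cluster.hierarchy import linkage

        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        vecs = {f"L{k}": X[k] for k in range(6)}
        names, D = gvalue_distance_matrix(vecs)
        ours = ward_cluster(D, labels=names)
        Z = linkage(X, method="ward")
        # scipy's ward heights h satisfy h^2 / 2 = SSE increase
        assert np.allclose(sorted(ours.heights()), sorted(Z[:, 2] ** 2 / 2),
                           atol=1e-8)

    @given(st.integers(0, 10_000), st.integers(3, 9))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_heights(self, seed, n_leaves):
        rng = np.random.default_rng(seed)
        vecs = {f"L{k}": rng.normal(size=3) for k in range(n_leaves)}
        names, D = gvalue_distance_matrix(vecs)
        h = ward_cluster(D, labels=names).heights()
        assert np.all(np.diff(h) >= -1e-10)

    def test_invalid_distances_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError):
            ward_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestGenicSignalSeparation:
    def test_genic_regions_cluster_apart_from_intergenic(self):
        """With effects concentrated in genic SNPs, the predicted genetic
        values of the four genic kernels cluster together and the intergenic
        kernels join last, in at least 12 of 15 simulation replicates."""
        from regionpred import annotate, kernel, krr
        from regionpred.simulate import (TraitArchitecture, simulate_genome,
                                         simulate_genotypes, simulate_phenotypes)

        genic = frozenset(("CDS", "Exons", "Genes", "Genes1kb"))
        hits = 0
        for seed in range(15):
            genome = simulate_genome(2, 500_000, 6, 2e-3, seed=seed)
            geno = simulate_genotypes(200, genome.snp_map, seed=seed + 1000)
            part = annotate.build_partition(genome.snp_map, genome)
            pheno, _ = simulate_phenotypes(
                geno, part, TraitArchitecture("Genes", h2=0.4), seed=seed + 2000)
            y = pheno["y"].to_numpy()
            y = y - y.mean()
            ghat = {}
            for i, name in enumerate(sorted(genic) + ["IGR"]):
                km = kernel.vanraden_g(geno, part[name])
                ghat[name] = krr.gibbs_krr(
                    y, km, config=krr.MCMCConfig.reduced(seed=seed + 3000 + i)).ghat
            sample = annotate.sample_matched_igr(part, "CDS", seed=seed + 4000)
            km = kernel.vanraden_g(geno, sample.snp_ids)
            ghat["MatchedIGR"] = krr.gibbs_krr(
                y, km, config=krr.MCMCConfig.reduced(seed=seed + 5000)).ghat
            names, D = gvalue_distance_matrix(ghat)
            split = ward_cluster(D, labels=names).root_split()
            if genic in split:
                hits += 1
        assert hits >= 12


class TestNewick:
    def test_two_leaf_string(self):
        d = Dendrogram(["A", "B"], [("A", "B", 8.0)])
        assert write_newick(d) == "(A:4,B:4);"

    def test_three_leaf_exact_string(self):
        d = Dendrogram(["A", "B", "C"], [("A", "B", 2.0), ("(A+B)", "C", 6.0)])
        assert write_newick(d) == "((A:1,B:1):2,C:3);"

    def test_round_trip_through_newick_reader(self):
        rng = np.random.default_rng(5)
        vecs = {f"L{k}": rng.normal(size=4) for k in range(5)}
        names, D = gvalue_distance_matrix(vecs)
        dendro = ward_cluster(D, labels=names)
        nwk = write_newick(dendro)
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
        assert leaves == sorted(names)
        # ultrametric: all root-to-leaf path lengths equal half the last merge
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert np.allclose(depths, dendro.merges[-1][2] / 2, atol=1e-9)
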