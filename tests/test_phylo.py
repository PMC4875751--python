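"""JTT model, ML distances, neighbor joining, bootstrap, coherence."""

import numpy as np
import pytest

from ortho_signature.errors import UndefinedDistanceError, ValidationError
from ortho_signature.jtt import JTT_ORDER, default_model
from ortho_signature.phylo import (DistanceMatrix, bipartitions, bootstrap_support,
                                   clade_coherence, collapse_low_support,
                                   distance_matrix, jtt_pairwise_distance,
                                   neighbor_joining)
from ortho_signature.synth import evolve_branch, sample_equilibrium


class TestJTTModel:
    def test_rate_matrix_properties(self):
        m = default_model()
        assert np.abs(m.Q.sum(axis=1)).max() < 1e-10
        assert np.abs(m.pi @ m.Q).max() < 1e-12          # stationarity
        flux = m.pi[:, None] * m.Q
        assert np.abs(flux - flux.T).max() < 1e-12       # detailed balance
        assert np.dot(m.pi, -np.diag(m.Q)) == pytest.approx(1.0)  # unit rate

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_transition_matrix_stochastic(self, t):
        P = default_model().transition_matrix(t)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
        assert P.min() >= 0.0

    def test_p_zero_is_identity(self):
        assert np.abs(default_model().transition_matrix(0.0) - np.eye(20)).max() < 1e-10

    def test_matches_scipy_expm(self):
        from scipy.linalg import expm
        m = default_model()
        for t in (0.05, 0.5, 2.0):
            assert np.abs(m.transition_matrix(t) - expm(m.Q * t)).max() < 1e-10


class TestPairwiseDistance:
    def test_identical_sequences_zero(self):
        assert jtt_pairwise_distance("MKRDE", "MKRDE") == 0.0

    def test_symmetric_by_reversibility(self):
        a, b = "MKRDEYWQHILK", "MDRDEYWAHILR"
        assert jtt_pairwise_distance(a, b) == pytest.approx(
            jtt_pairwise_distance(b, a), abs=1e-6)

    def test_no_shared_columns_is_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            jtt_pairwise_distance("MK--", "--DE")

    def test_gapped_columns_excluded(self):
        # distance determined only by the shared (non-gap) columns
        d1 = jtt_pairwise_distance("MKRDE", "MKRDE")
        d2 = jtt_pairwise_distance("MKRDE-W", "MKRDEY-")
        assert d1 == d2 == 0.0

    def test_simulation_recovery_with_grid_oracle(self):
        """Median ML estimate over replicates at t=0.3 falls in [0.2, 0.4],
        and the scalar optimiser agrees with a brute-force likelihood grid."""
        m = default_model()
        rng = np.random.default_rng(42)
        ests = []
        for _ in range(50):
            root = sample_equilibrium(100, rng, m)
            child = evolve_branch(root, 0.3, rng, m)
            a = "".join(JTT_ORDER[s] for s in root)
            b = "".join(JTT_ORDER[s] for s in child)
            ests.append(jtt_pairwise_distance(a, b, m))
        assert 0.2 <= np.median(ests) <= 0.4
        # grid oracle on the last pair
        grid = np.linspace(0.01, 2.0, 400)
        idx = {ch: i for i, ch in enumerate(JTT_ORDER)}
        N = np.zeros((20, 20))
        for x, y in zip(a, b):
            N[idx[x], idx[y]] += 1
        lls = [np.sum(N * np.log(np.maximum(m.transition_matrix(t), 1e-300)))
               for t in grid]
        t_grid = grid[int(np.argmax(lls))]
        assert ests[-1] == pytest.approx(t_grid, abs=0.01)

    def test_monotone_in_observed_differences(self):
        m = default_model()
        rng = np.random.default_rng(1)
        root = sample_equilibrium(400, rng, m)
        a = "".join(JTT_ORDER[s] for s in root)
        dists = []
        for t in (0.05, 0.2, 0.6, 1.2):
            child = evolve_branch(root, t, rng, m)
            dists.append(jtt_pairwise_distance(a, "".join(JTT_ORDER[s] for s in child), m))
        assert dists == sorted(dists)


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # additive distances from ((A:1,B:2):1,(C:3,D:4))
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels=["A", "B", "C", "D"], d=d))
        sides = set(bipartitions(tree))
        assert frozenset({"C", "D"}) in sides  # the AB|CD split
        lens = {}
        for lf in tree.leaf_node_iter():
            lens[lf.taxon.label] = lf.edge.length
        assert lens == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        internal = [e.length for e in tree.preorder_edge_iter()
                    if e.length and e.head_node and not e.head_node.is_leaf()]
        assert internal == pytest.approx([1.0])

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels=["A", "B", "C"], d=d))
        lens = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lens == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_matches_skbio_on_random_matrices(self):
        """Independent oracle: same topology as scikit-bio's NJ."""
        import dendropy
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = 7
            base = rng.uniform(0.1, 1.0, size=(n, n))
            d = (base + base.T) / 2
            np.fill_diagonal(d, 0.0)
            labels = [f"t{i}" for i in range(n)]
            mine = neighbor_joining(DistanceMatrix(labels=labels, d=d))
            sk = dendropy.Tree.get(data=str(sknj(SkDM(d, ids=labels))),
                                   schema="newick", preserve_underscores=True)
            assert set(bipartitions(mine)) == set(bipartitions(sk))

    def test_requires_three_taxa_and_valid_matrix(self):
        with pytest.raises(ValidationError):
            neighbor_joining(DistanceMatrix(labels=["A", "B"], d=np.zeros((2, 2))))
        with pytest.raises(ValidationError):
            DistanceMatrix(labels=["A", "B", "C"],
                           d=np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))


class TestBootstrap:
    def test_perfectly_consistent_columns_give_full_support(self):
        from ortho_signature.seqio import MasterAlignment
        rows = {"A": "", "B": "", "C": "", "D": ""}
        rng = np.random.default_rng(0)
        for _ in range(200):
            # AB share one residue, CD another: tree-consistent signal
            r1, r2 = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=2, replace=False)
            rows["A"] += r1
            rows["B"] += r1
            rows["C"] += r2
            rows["D"] += r2
        aln = MasterAlignment(ids=list(rows), rows=list(rows.values()))
        tree = bootstrap_support(aln, 50, seed=1)
        sups = [nd.support for nd in bipartitions(tree).values()]
        assert sups == [100.0]

    def test_supports_in_range_and_leaf_order_invariant(self, small_family):
        aln = small_family.alignment.subset(small_family.alignment.ids[:6])
        t1 = bootstrap_support(aln, 30, seed=5)
        s1 = {b: nd.support for b, nd in bipartitions(t1).items()}
        assert all(0.0 <= v <= 100.0 for v in s1.values())
        shuffled = aln.subset(list(reversed(aln.ids)))
        t2 = bootstrap_support(shuffled, 30, seed=5)
        s2 = {b: nd.support for b, nd in bipartitions(t2).items()}
        assert set(s1) == set(s2)

    def test_two_seeds_within_binomial_noise(self, small_family):
        aln = small_family.alignment.subset(small_family.alignment.ids[:5])
        t1 = bootstrap_support(aln, 100, seed=1)
        t2 = bootstrap_support(aln, 100, seed=2)
        s1 = {b: nd.support for b, nd in bipartitions(t1).items()}
        s2 = {b: nd.support for b, nd in bipartitions(t2).items()}
        for b in set(s1) & set(s2):
            assert abs(s1[b] - s2[b]) <= 15.0

    def test_seed_reproducible(self, small_family):
        aln = small_family.alignment.subset(small_family.alignment.ids[:5])
        s1 = {b: nd.support for b, nd in
              bipartitions(bootstrap_support(aln, 25, seed=9)).items()}
        s2 = {b: nd.support for b, nd in
              bipartitions(bootstrap_support(aln, 25, seed=9)).items()}
        assert s1 == s2


class TestCollapse:
    def _supported_tree(self, small_family):
        aln = small_family.alignment.subset(small_family.alignment.ids[:8])
        return bootstrap_support(aln, 25, seed=2)

    def test_threshold_zero_is_identity(self, small_family):
        t = self._supported_tree(small_family)
        assert set(bipartitions(collapse_low_support(t, 0.0))) == set(bipartitions(t))

    def test_everything_below_threshold_gives_star(self, small_family):
        t = self._supported_tree(small_family)
        star = collapse_low_support(t, 101.0)
        assert bipartitions(star) == {}
        assert sorted(l.taxon.label for l in star.leaf_node_iter()) == \
            sorted(l.taxon.label for l in t.leaf_node_iter())

    def test_collapse_composition_idempotent(self, small_family):
        t = self._supported_tree(small_family)
        via70 = collapse_low_support(collapse_low_support(t, 70.0), 90.0)
        direct = collapse_low_support(t, 90.0)
        assert set(bipartitions(via70)) == set(bipartitions(direct))


class TestCladeCoherence:
    def test_separated_groups_on_caterpillar(self):
        d = np.array([[0, 1, 5, 5.5], [1, 0, 5.5, 6], [5, 5.5, 0, 1], [5.5, 6, 1, 0]],
                     float)
        t = neighbor_joining(DistanceMatrix(labels=["a1", "a2", "b1", "b2"], d=d))
        res = clade_coherence(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert res == {"A": True, "B": True}

    def test_swapped_leaf_breaks_coherence(self):
        d = np.array([
            [0, 1, 5, 5.5, 6], [1, 0, 5.5, 6, 6.5], [5, 5.5, 0, 1, 1.5],
            [5.5, 6, 1, 0, 1.8], [6, 6.5, 1.5, 1.8, 0]], float)
        t = neighbor_joining(DistanceMatrix(labels=["a1", "a2", "b1", "b2", "b3"], d=d))
        res = clade_coherence(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "A"})
        assert res["A"] is False

    def test_missing_assignment_raises(self):
        from ortho_signature.errors import LookupMissingError
        d = np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], float)
        t = neighbor_joining(DistanceMatrix(labels=["a", "b", "c"], d=d))
        with pytest.raises(LookupMissingError):
            clade_coherence(t, {"a": "A", "b": "B"})


class TestDeletionModes:
    def test_complete_deletion_drops_gapped_columns(self):
        from ortho_signature.seqio import MasterAlignment
        aln = MasterAlignment(ids=["a", "b", "c"],
                              rows=["MKRDE", "MKRD-", "MKRDE"])
        dp = distance_matrix(aln, deletion="pairwise")
        dc = distance_matrix(aln, deletion="complete")
        assert dp.d[0, 2] == dc.d[0, 2] == 0.0
        with pytest.raises(ValidationError):
            distance_matrix(aln, deletion="jackknife")
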