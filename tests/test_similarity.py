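"""KL / edit-distance / KDE sample similarities, clustering, entropy."""

import numpy as np
import pytest

from elate.io_encoding import RepertoireSample, TCRClone
from elate.similarity import (
    ClusterAssignment,
    SampleSimilarityMatrix,
    cluster_entropy,
    ed_similarity,
    hierarchical_cluster,
    kde_similarity_matrix,
    kl_similarity,
)

from conftest import random_clones


def levenshtein_dp(s: str, t: str) -> int:
    """Textbook dynamic-programming edit distance; the oracle."""
    prev = list(range(len(t) + 1))
    for i, a in enumerate(s, 1):
        cur = [i]
        for j, b in enumerate(t, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (a != b)))
        prev = cur
    return prev[-1]


def _sample(cdr3s, v_genes=None, sample_id="s", category=""):
    clones = [
        TCRClone(c, v_gene=None if v_genes is None else v_genes[i]) for i, c in enumerate(cdr3s)
    ]
    return RepertoireSample(sample_id, clones, category)


class TestKLSimilarity:
    def test_identical_distribution_is_zero(self):
        a = _sample(["CASSF"] * 50, ["TRBV1"] * 25 + ["TRBV2"] * 25, "a")
        b = _sample(["CASRF"] * 50, ["TRBV1"] * 25 + ["TRBV2"] * 25, "b")
        assert kl_similarity(a, b, r=50, seed=0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value_without_smoothing(self):
        # p = (1, 0), q = (0.5, 0.5) on the same support; pseudocount off
        a = _sample(["CASSF"] * 40, ["TRBV1"] * 40, "a")
        b = _sample(["CASRF"] * 40, ["TRBV1"] * 20 + ["TRBV2"] * 20, "b")
        val = kl_similarity(a, b, r=40, seed=0, pseudocount=1e-12)
        assert val == pytest.approx(np.log(2), abs=1e-6)

    def test_nonnegative_over_random_pairs(self, rng):
        vs = [f"TRBV{i}" for i in range(5)]
        for _ in range(100):
            va = [vs[i] for i in rng.integers(0, 5, size=30)]
            vb = [vs[i] for i in rng.integers(0, 5, size=30)]
            a = _sample(["CASSF"] * 30, va, "a")
            b = _sample(["CASRF"] * 30, vb, "b")
            assert kl_similarity(a, b, r=30, seed=int(rng.integers(0, 1000))) >= -1e-12

    def test_requires_v_genes(self):
        a = _sample(["CASSF"] * 3)
        with pytest.raises(ValueError):
            kl_similarity(a, a, r=3)


class TestEDSimilarity:
    def test_matches_dp_oracle_on_random_pairs(self, rng):
        import edlib

        clones = random_clones(rng, 1000, min_len=4, max_len=15)
        for i in range(500):
            s, t = clones[2 * i].cdr3, clones[2 * i + 1].cdr3
            assert edlib.align(s, t, task="distance")["editDistance"] == levenshtein_dp(s, t)

    def test_hand_example_row_minima(self):
        a = _sample(["CASS"], sample_id="a")
        b = _sample(["CAST", "CKSS"], sample_id="b")
        assert ed_similarity(a, b, r=2, strict=False) == 1.0

    def test_subset_gives_zero(self):
        a = _sample(["CASSF", "CARGF"], sample_id="a")
        b = _sample(["CASSF", "CARGF", "CQQQF"], sample_id="b")
        assert ed_similarity(a, b, r=3, strict=False) == 0.0

    def test_self_mode_excludes_diagonal(self):
        a = _sample(["CASSF", "CASTF", "CARGW"], sample_id="a")
        val = ed_similarity(a, a, r=3, strict=False)
        # nearest neighbours: CASSF<->CASTF at 1, CARGW at 3 -> mean 5/3
        assert val == pytest.approx((1 + 1 + 3) / 3)
        assert val > 0


class TestKDEMatrix:
    def test_entries_match_individual_calls(self, small_trained_e, host_samples):
        from elate.density import sample_cross_similarity

        m = kde_similarity_matrix(host_samples[:2], small_trained_e, r=50, seed=9)
        expect01 = sample_cross_similarity(host_samples[0], host_samples[1], small_trained_e, r=50, seed=9 + 7919)
        assert m.values[0, 1] == expect01

    def test_within_host_exceeds_between_host(self, small_trained_e, host_samples):
        m = kde_similarity_matrix(host_samples, small_trained_e, r=80, seed=4)
        cats = [s.category for s in host_samples]
        within, between = [], []
        for i in range(len(cats)):
            for j in range(len(cats)):
                if i == j:
                    continue
                (within if cats[i] == cats[j] else between).append(m.values[i, j])
        assert np.mean(within) > np.mean(between)


class TestHierarchicalCluster:
    def _blob_matrix(self):
        # two planted blocks of samples: near distance 1 within, 10 between
        ids = [f"s{i}" for i in range(6)]
        d = np.full((6, 6), 10.0)
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    d[i, j] = 0.0 if i == j else 1.0
        return SampleSimilarityMatrix(ids, d, "ED", direction="distance")

    def test_planted_partition_recovered(self):
        assignment = hierarchical_cluster(self._blob_matrix(), k=2)
        labels = assignment.labels
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_k_equals_n_gives_singletons(self):
        assignment = hierarchical_cluster(self._blob_matrix(), k=6)
        assert assignment.n_clusters == 6

    def test_linkage_heights_monotone(self):
        link = hierarchical_cluster(self._blob_matrix(), k=2).linkage
        assert np.all(np.diff(link[:, 2]) >= -1e-12)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(self._blob_matrix(), k=7)

    def test_newick_export_parses(self):
        assignment = hierarchical_cluster(self._blob_matrix(), k=2)
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(assignment.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == [f"s{i}" for i in range(6)]


class TestClusterEntropy:
    def _assignment(self, labels):
        return ClusterAssignment(
            sample_ids=[f"s{i}" for i in range(len(labels))],
            labels=np.asarray(labels),
            linkage=np.zeros((0, 4)),
        )

    def test_pure_labels_have_zero_entropy(self):
        a = self._assignment([1, 1, 2, 2])
        per_label, mean = cluster_entropy(a, {"s0": "x", "s1": "x", "s2": "y", "s3": "y"})
        assert per_label == {"x": 0.0, "y": 0.0} and mean == 0.0

    def test_even_split_is_one_bit(self):
        a = self._assignment([1, 2])
        per_label, _ = cluster_entropy(a, {"s0": "x", "s1": "x"})
        assert per_label["x"] == pytest.approx(1.0)

    def test_invariant_under_cluster_relabeling(self):
        labels = {"s0": "x", "s1": "x", "s2": "y", "s3": "y"}
        a = self._assignment([1, 2, 2, 2])
        b = self._assignment([5, 3, 3, 3])
        assert cluster_entropy(a, labels) == cluster_entropy(b, labels)

    def test_missing_labels_error(self):
        with pytest.raises(ValueError):
            cluster_entropy(self._assignment([1]), {})
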