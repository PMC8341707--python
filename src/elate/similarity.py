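"""Sample-by-sample similarity matrices, clustering and cluster entropy.

Three similarity notions between repertoire samples:

* **KDE** — mean embedded density of one sample's clones with respect to the
  other's (directional; higher = closer).
* **KL** — Kullback-Leibler divergence between V-gene usage distributions of
  seeded subsamples (a distance; lower = closer).
* **ED** — mean over one sample's subsampled CDR3s of the Levenshtein
  distance to the nearest CDR3 of the other sample (a distance; the diagonal
  of the within-sample matrix is excluded for self-comparison).

Matrices feed average-linkage hierarchical clustering; how well a labelling
(host, time point) is captured by the resulting clusters is summarized by
the Shannon entropy of each label's distribution over clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from elate.autoencoder import TrainedAE
from elate.density import sample_cross_similarity
from elate.io_encoding import RepertoireSample

_EPS = np.finfo(float).tiny


@dataclass
class SampleSimilarityMatrix:
    """Square pairwise matrix over ordered sample ids.

    ``direction`` records whether larger values mean closer samples
    ("similarity", the KDE case) or farther ("distance", KL and ED).
    """

    sample_ids: list[str]
    values: np.ndarray
    method: str
    direction: str = "similarity"

    def __post_init__(self) -> None:
        k = len(self.sample_ids)
        if self.values.shape != (k, k):
            raise ValueError("matrix must be square over the sample ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def as_distance(self) -> np.ndarray:
        """Symmetric distance form used for linkage.

        Similarities become distances via -log (floored at the smallest
        positive float); asymmetric matrices are symmetrized by averaging the
        two directions and the diagonal is zeroed.
        """
        if self.direction == "similarity":
            d = -np.log(np.maximum(self.values, _EPS))
            d -= d.min()  # shift so distances are nonnegative
        else:
            d = self.values.copy()
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class ClusterAssignment:
    """Flat cluster labels per sample plus the underlying linkage tree."""

    sample_ids: list[str]
    labels: np.ndarray
    linkage: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def to_newick(self) -> str:
        """Dendrogram in Newick form with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# pairwise similarities


def kl_similarity(
    p_sample: RepertoireSample,
    q_sample: RepertoireSample,
    r: int = 100,
    seed: int = 0,
    pseudocount: float = 1.0,
    strict: bool = False,
) -> float:
    """KL divergence D(p||q) between V-usage distributions of two samples.

    V counts come from ``r`` seeded subsampled clones per sample; an additive
    pseudocount on the counts (over the union of observed V genes) keeps
    q(v) > 0.  Natural logarithm.
    """
    if not p_sample.has_v or not q_sample.has_v:
        raise ValueError("KL similarity requires V genes on both samples")
    rng = np.random.default_rng(seed)
    p_clones = p_sample.subsample(r, rng, strict=strict).clones
    q_clones = q_sample.subsample(r, rng, strict=strict).clones
    v_names = sorted({c.v_gene for c in p_clones} | {c.v_gene for c in q_clones})
    idx = {v: i for i, v in enumerate(v_names)}
    p = np.full(len(v_names), pseudocount)
    q = np.full(len(v_names), pseudocount)
    for c in p_clones:
        p[idx[c.v_gene]] += 1
    for c in q_clones:
        q[idx[c.v_gene]] += 1
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def ed_similarity(
    a: RepertoireSample,
    b: RepertoireSample,
    r: int = 100,
    seed: int = 0,
    strict: bool = False,
) -> float:
    """Mean nearest-neighbour Levenshtein distance from ``a``'s CDR3s to ``b``'s.

    Builds the r x r edit-distance matrix between seeded subsamples and
    averages the row minima; for self-comparison (``a is b``) the diagonal is
    excluded.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    rng = np.random.default_rng(seed)
    rows = a.subsample(r, rng, strict=strict).cdr3s()
    cols = rows if a is b else b.subsample(r, rng, strict=strict).cdr3s()
    e = np.empty((len(rows), len(cols)))
    for i, s in enumerate(rows):
        for j, t in enumerate(cols):
            e[i, j] = edlib.align(s, t, task="distance")["editDistance"]
    if a is b:
        if len(rows) < 2:
            raise ValueError("self edit-distance needs at least 2 clones")
        np.fill_diagonal(e, np.inf)
    return float(e.min(axis=1).mean())


def kde_similarity_matrix(
    samples: list[RepertoireSample],
    model: TrainedAE,
    r: int = 100,
    use_freq: bool = False,
    seed: int = 0,
    strict: bool = True,
) -> SampleSimilarityMatrix:
    """Directional KDE similarity between every ordered pair of samples.

    Entry (i, j) is the mean density of sample i's subsampled projections
    with respect to sample j's; the matrix is not symmetric in general.
    """
    k = len(samples)
    values = np.zeros((k, k))
    for i, a in enumerate(samples):
        for j, b in enumerate(samples):
            pair_seed = seed + 1000003 * min(i, j) + 7919 * max(i, j)
            values[i, j] = sample_cross_similarity(
                a, b if i != j else a, model, r=r, use_freq=use_freq, seed=pair_seed, strict=strict
            )
    return SampleSimilarityMatrix(
        sample_ids=[s.sample_id for s in samples], values=values, method="KDE", direction="similarity"
    )


def kl_similarity_matrix(samples: list[RepertoireSample], r: int = 100, seed: int = 0) -> SampleSimilarityMatrix:
    k = len(samples)
    values = np.zeros((k, k))
    for i, a in enumerate(samples):
        for j, b in enumerate(samples):
            if i != j:
                values[i, j] = kl_similarity(a, b, r=r, seed=seed + 1000003 * min(i, j) + 7919 * max(i, j))
    return SampleSimilarityMatrix(
        sample_ids=[s.sample_id for s in samples], values=values, method="KL", direction="distance"
    )


def ed_similarity_matrix(samples: list[RepertoireSample], r: int = 100, seed: int = 0) -> SampleSimilarityMatrix:
    k = len(samples)
    values = np.zeros((k, k))
    for i, a in enumerate(samples):
        for j, b in enumerate(samples):
            values[i, j] = ed_similarity(
                a, b if i != j else a, r=r, seed=seed + 1000003 * min(i, j) + 7919 * max(i, j)
            )
    return SampleSimilarityMatrix(
        sample_ids=[s.sample_id for s in samples], values=values, method="ED", direction="distance"
    )


# ---------------------------------------------------------------------------
# clustering and entropy


def hierarchical_cluster(matrix: SampleSimilarityMatrix, k: int) -> ClusterAssignment:
    """Average-linkage agglomeration on the distance form of the matrix."""
    n = len(matrix.sample_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    d = matrix.as_distance()
    condensed = d[np.triu_indices(n, k=1)]
    link = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return ClusterAssignment(sample_ids=list(matrix.sample_ids), labels=labels, linkage=link)


def cluster_entropy(assignment: ClusterAssignment, labels: dict[str, str]) -> tuple[dict[str, float], float]:
    """Shannon entropy (bits) of each label's spread over clusters.

    ``labels`` maps sample id -> category.  Returns per-label entropies and
    their unweighted mean; a label confined to one cluster scores 0.
    """
    if len(assignment.sample_ids) == 0:
        raise ValueError("empty assignment")
    missing = [s for s in assignment.sample_ids if s not in labels]
    if missing:
        raise ValueError(f"labels missing for samples {missing}")
    per_label: dict[str, float] = {}
    for label in sorted(set(labels[s] for s in assignment.sample_ids)):
        clusters = [c for s, c in zip(assignment.sample_ids, assignment.labels) if labels[s] == label]
        _, counts = np.unique(clusters, return_counts=True)
        p = counts / counts.sum()
        per_label[label] = float(-(p * np.log2(p)).sum() + 0.0)  # +0.0 clears -0.0
    return per_label, float(np.mean(list(per_label.values())))
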