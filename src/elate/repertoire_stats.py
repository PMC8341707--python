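"""Descriptive embedding-space analyses of repertoires.

Publicity (how many samples carry a clone), radius from the center of mass
of all projections, mean self-density of clones grouped by amino-acid
content, rank correlations between such per-clone statistics, and a seeded
t-SNE export for 2-D visualization.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr, ttest_ind
from sklearn.manifold import TSNE

from elate.autoencoder import TrainedAE, embed
from elate.density import self_density
from elate.io_encoding import RepertoireSample


def publicity(samples: list[RepertoireSample], by_v: bool = False) -> dict:
    """Number of samples whose clone set contains each distinct clone.

    Identity is the exact CDR3 string by default; ``by_v=True`` switches to
    (CDR3, V) pairs.
    """
    if not samples:
        raise ValueError("need at least one sample")
    counts: Counter = Counter()
    for sample in samples:
        keys = {(c.cdr3, c.v_gene) if by_v else c.cdr3 for c in sample}
        counts.update(keys)
    return dict(counts)


def radius_from_center(embeddings: np.ndarray) -> np.ndarray:
    """Euclidean distance of each embedding from the unweighted mean."""
    e = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    return np.linalg.norm(e - e.mean(axis=0), axis=1)


@dataclass
class FeatureDensityResult:
    """Mean log self-density per residue-count group plus a two-group t-test."""

    residue: str
    group_counts: list[int]
    group_sizes: list[int]
    group_means: list[float]
    t_statistic: float | None
    p_value: float | None


def feature_density(
    sample: RepertoireSample,
    model: TrainedAE,
    residue: str,
    counts: list[int] | None = None,
    offset: int | None = None,
) -> FeatureDensityResult:
    """Mean leave-self-out log density of clones grouped by residue content.

    Clones are partitioned by how many times ``residue`` occurs in the CDR3
    starting at position ``offset`` (default 1 for cysteine — occurrences
    beyond the first, conserved, position — and 0 otherwise).  The t-test
    compares the first two non-empty groups.
    """
    if residue not in "ACDEFGHIKLMNPQRSTVWY":
        raise ValueError(f"{residue!r} is not a standard amino acid")
    if offset is None:
        offset = 1 if residue == "C" else 0
    z = embed(model, sample.clones)
    log_d = self_density(z).log_values
    occ = np.array([c.cdr3[offset:].count(residue) for c in sample.clones])
    if counts is None:
        counts = sorted(set(occ.tolist()))
    groups = [log_d[occ == c] for c in counts]
    kept = [(c, g) for c, g in zip(counts, groups) if len(g) > 0]
    if len(kept) < len(counts):
        import warnings

        warnings.warn(f"{residue}: skipped empty groups {[c for c, g in zip(counts, groups) if len(g) == 0]}")
    t_stat = p_val = None
    if len(kept) >= 2:
        t_stat, p_val = ttest_ind(kept[0][1], kept[1][1], equal_var=False)
        t_stat, p_val = float(t_stat), float(p_val)
    return FeatureDensityResult(
        residue=residue,
        group_counts=[c for c, _ in kept],
        group_sizes=[len(g) for _, g in kept],
        group_means=[float(g.mean()) for _, g in kept],
        t_statistic=t_stat,
        p_value=p_val,
    )


def correlate(stat_x: np.ndarray, stat_y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation between two aligned per-clone statistics."""
    x = np.asarray(stat_x, dtype=np.float64)
    y = np.asarray(stat_y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be aligned 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 clones")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


def project_2d(embeddings: np.ndarray, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """Seeded t-SNE of the 30-dimensional embeddings down to 2-D."""
    e = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    if e.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (e.shape[0] - 1) / 3.0))
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return tsne.fit_transform(e)
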