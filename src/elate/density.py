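"""Gaussian kernel density estimates over embedded repertoires.

The density of a query embedding x with respect to a reference set
{y_1..y_R} is

    f_h(x) = 1/(R h) * sum_i w_i K((x - y_i) / h)

with K the radial Gaussian kernel K(u) = (2 pi)^(-Z/2) exp(-||u||^2 / 2) in
Z = 30 dimensions, w_i = 1 for the unweighted estimate or w_i = freq_i when
clone sizes weight the reference, and the bandwidth

    h = 1.06 * STD(S) * |S|^(-1/5)

where STD(S) is the mean of the per-dimension standard deviations of the
reference set.  The 1/(R h) prefactor is the literal published form; a
``fully_normalized`` switch replaces it by 1/(R h^Z), the prefactor that
makes f_h integrate to one — all comparative results are invariant to this
constant.  Self-density of a sample is the same estimate against itself with
each point's own kernel term left out.

Densities are computed and stored in log space for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from elate.autoencoder import TrainedAE, embed
from elate.io_encoding import RepertoireSample


@dataclass
class DensityEstimate:
    """Per-query-point densities (log-space) plus the bandwidth used."""

    log_values: np.ndarray
    h: float
    weighted: bool = False

    @property
    def values(self) -> np.ndarray:
        """Densities on the linear scale (always positive for a Gaussian kernel)."""
        return np.exp(self.log_values)

    def __len__(self) -> int:
        return len(self.log_values)


def bandwidth(s: np.ndarray, std_mode: str = "per_dimension") -> float:
    """Rule-of-thumb bandwidth h = 1.06 * STD(S) * |S|^(-1/5).

    ``std_mode="per_dimension"`` (default) takes STD(S) as the mean of the
    per-dimension standard deviations; ``"global"`` uses the standard
    deviation of the flattened matrix.
    """
    s = np.atleast_2d(np.asarray(s, dtype=np.float64))
    if s.shape[0] < 2:
        raise ValueError("bandwidth needs at least 2 points")
    if std_mode == "per_dimension":
        std = float(s.std(axis=0).mean())
    elif std_mode == "global":
        std = float(s.std())
    else:
        raise ValueError("std_mode must be 'per_dimension' or 'global'")
    if std == 0.0:
        raise ValueError("degenerate reference set: zero spread")
    return 1.06 * std * len(s) ** (-1.0 / 5.0)


def _log_kde(
    queries: np.ndarray,
    refs: np.ndarray,
    h: float,
    freq: np.ndarray | None,
    exclude_self: bool,
    fully_normalized: bool,
) -> np.ndarray:
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    refs = np.atleast_2d(np.asarray(refs, dtype=np.float64))
    if queries.shape[1] != refs.shape[1]:
        raise ValueError(f"dimension mismatch: {queries.shape[1]} vs {refs.shape[1]}")
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    r = refs.shape[0]
    z = refs.shape[1]
    log_w = np.zeros(r)
    if freq is not None:
        freq = np.asarray(freq, dtype=np.float64)
        if freq.shape != (r,):
            raise ValueError("freq must align with the reference set")
        if np.any(freq <= 0):
            raise ValueError("frequencies must be positive")
        log_w = np.log(freq)
    sq = cdist(queries, refs, metric="sqeuclidean") / h**2
    log_terms = -0.5 * sq - 0.5 * z * np.log(2.0 * np.pi) + log_w[None, :]
    if exclude_self:
        if queries.shape != refs.shape:
            raise ValueError("leave-self-out requires queries identical to references")
        np.fill_diagonal(log_terms, -np.inf)
    prefactor = -np.log(r) - (z if fully_normalized else 1) * np.log(h)
    return logsumexp(log_terms, axis=1) + prefactor


def cross_density(
    s1: np.ndarray,
    s2: np.ndarray,
    h: float | None = None,
    freq: np.ndarray | None = None,
    fully_normalized: bool = False,
) -> DensityEstimate:
    """Density of each embedding in ``s1`` with respect to the set ``s2``.

    ``freq`` (aligned with ``s2``) weights each reference clone by its size.
    When ``h`` is omitted it is derived from ``s2`` by the bandwidth rule.
    """
    if h is None:
        h = bandwidth(s2)
    log_vals = _log_kde(s1, s2, h, freq, exclude_self=False, fully_normalized=fully_normalized)
    return DensityEstimate(log_values=log_vals, h=h, weighted=freq is not None)


def self_density(
    s: np.ndarray,
    h: float | None = None,
    freq: np.ndarray | None = None,
    fully_normalized: bool = False,
) -> DensityEstimate:
    """Leave-self-out density of each embedding against its own sample."""
    s = np.atleast_2d(np.asarray(s, dtype=np.float64))
    if s.shape[0] < 2:
        raise ValueError("self-density needs at least 2 points")
    if h is None:
        h = bandwidth(s)
    log_vals = _log_kde(s, s, h, freq, exclude_self=True, fully_normalized=fully_normalized)
    return DensityEstimate(log_values=log_vals, h=h, weighted=freq is not None)


def sample_cross_similarity(
    a: RepertoireSample,
    b: RepertoireSample,
    model: TrainedAE,
    r: int = 100,
    use_freq: bool = False,
    seed: int = 0,
    strict: bool = True,
) -> float:
    """KDE similarity of sample ``a`` given sample ``b`` (directional).

    Subsamples ``r`` clones per sample (seeded, without replacement; a
    constant subsample size avoids sample-size bias), embeds both, takes the
    bandwidth from ``b``'s projections and returns the mean density of
    ``a``'s projections with respect to ``b``'s.  Self-comparison (same
    sample id and identical clone list) leaves each clone's own kernel term
    out.
    """
    rng = np.random.default_rng(seed)
    sub_a = a.subsample(r, rng, strict=strict)
    sub_b = b.subsample(r, rng, strict=strict) if a is not b else sub_a
    za = embed(model, sub_a.clones)
    freq = None
    if use_freq:
        if not b.has_frequency:
            raise ValueError(f"sample {b.sample_id} carries no frequencies")
        freq = np.array([c.frequency for c in sub_b.clones])
    if a is b:
        est = self_density(za, freq=freq)
    else:
        zb = embed(model, sub_b.clones)
        est = cross_density(za, zb, freq=freq)
    # mean density on the linear scale, computed stably in log space
    return float(np.exp(logsumexp(est.log_values) - np.log(len(est))))
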