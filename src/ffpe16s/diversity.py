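"""Alpha/beta diversity, ordination and clustering for community tables.

Shannon entropy (natural log) for within-sample diversity; Bray-Curtis,
binary Jaccard and Jensen-Shannon divergence for between-sample
dissimilarity; classical principal coordinate analysis (Gower
double-centering) for ordination; and Ward hierarchical clustering for
sample grouping.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .data import AsvTable, DistanceMatrix, ValidationError


def _as_vector(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValidationError("expected a non-empty 1-D abundance vector")
    if (v < 0).any():
        raise ValidationError("negative abundance")
    return v


def shannon_index(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i over the non-zero proportions."""
    v = _as_vector(counts)
    total = v.sum()
    if total == 0:
        raise ValidationError("all-zero sample")
    p = v[v > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(x, y) -> float:
    """1 - 2 * sum(min(x_i, y_i)) / (sum x + sum y)."""
    x, y = _as_vector(x), _as_vector(y)
    if x.shape != y.shape:
        raise ValidationError("vectors must share a taxon index")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValidationError("both vectors all-zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def jaccard(x, y) -> float:
    """Binary Jaccard distance on presence/absence: 1 - |A&B| / |A|B|."""
    x, y = _as_vector(x), _as_vector(y)
    if x.shape != y.shape:
        raise ValidationError("vectors must share a taxon index")
    a, b = x > 0, y > 0
    union = (a | b).sum()
    if union == 0:
        raise ValidationError("both vectors empty")
    return float(1.0 - (a & b).sum() / union)


def jensen_shannon(x, y) -> float:
    """Jensen-Shannon divergence (natural log), in [0, ln 2].

    Inputs are normalised to proportions internally; the value returned is
    the divergence itself, not its square root.
    """
    x, y = _as_vector(x), _as_vector(y)
    if x.shape != y.shape:
        raise ValidationError("vectors must share a taxon index")
    if x.sum() == 0 or y.sum() == 0:
        raise ValidationError("cannot normalise an all-zero vector")
    p, q = x / x.sum(), y / y.sum()
    m = 0.5 * (p + q)

    def kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float((a[mask] * np.log(a[mask] / b[mask])).sum())

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


_METRIC_FUNCS = {
    "bray_curtis": bray_curtis,
    "jaccard": jaccard,
    "jensen_shannon": jensen_shannon,
}


def pairwise(x, y, metric: str) -> float:
    """One dissimilarity value under the named metric."""
    try:
        return _METRIC_FUNCS[metric](x, y)
    except KeyError:
        raise ValidationError(f"unknown metric {metric!r}") from None


def distance_matrix(table: AsvTable | pd.DataFrame, metric: str) -> DistanceMatrix:
    """All pairwise sample dissimilarities of a (count or percentage) table."""
    frame = table.counts if isinstance(table, AsvTable) else table
    samples = list(frame.columns)
    if len(samples) < 2:
        raise ValidationError("need at least two samples")
    if metric not in _METRIC_FUNCS:
        raise ValidationError(f"unknown metric {metric!r}")
    func = _METRIC_FUNCS[metric]
    n = len(samples)
    d = np.zeros((n, n))
    cols = frame.to_numpy().T
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = func(cols[i], cols[j])
    # JSD is bounded by ln 2 < 1, so [0, 1] holds for all three metrics.
    return DistanceMatrix(d, samples, metric)


@dataclasses.dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix.

    Axes with eigenvalues below tolerance (including the negative ones a
    semi-metric like Bray-Curtis can produce) are dropped; each retained
    axis's proportion of variance is its eigenvalue over the sum of
    positive eigenvalues.
    """

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x retained axes
    eigenvalues: np.ndarray  # retained, decreasing, > 0
    proportions: np.ndarray  # same length, sums to <= 1

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(d: DistanceMatrix, tol: float = 1e-9) -> PcoaResult:
    """Classical (metric) multidimensional scaling.

    Gower-centres -D^2/2, eigendecomposes, and keeps the axes with
    eigenvalues above ``tol`` times the largest.
    """
    n = len(d.sample_ids)
    if n < 3:
        raise ValidationError("PCoA needs at least three samples")
    a = -0.5 * d.values**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    cutoff = tol * max(eigval.max(), 1.0)
    keep = eigval > cutoff
    if not keep.any():
        warnings.warn("degenerate distance matrix: no positive PCoA axes")
        return PcoaResult(list(d.sample_ids), np.zeros((n, 0)), np.array([]), np.array([]))
    positive_total = eigval[eigval > 0].sum()
    lam = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(lam)
    return PcoaResult(list(d.sample_ids), coords, lam, lam / positive_total)


@dataclasses.dataclass
class Dendrogram:
    """Agglomerative merge list in scipy linkage format plus leaf labels."""

    labels: list[str]
    linkage: np.ndarray  # (n-1, 4): left, right, height, cluster size

    def first_bipartition(self) -> tuple[set[str], set[str]]:
        """Leaf labels of the two subtrees under the root merge."""
        n = len(self.labels)
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        for k, (left, right, _, _) in enumerate(self.linkage):
            members[n + k] = members[int(left)] | members[int(right)]
        left, right = int(self.linkage[-1, 0]), int(self.linkage[-1, 1])
        lab = np.array(self.labels)
        return set(lab[sorted(members[left])]), set(lab[sorted(members[right])])


def ward_clustering(table: pd.DataFrame, metric: str = "bray_curtis") -> Dendrogram:
    """Ward-linkage hierarchical clustering of samples on a community
    dissimilarity.

    ``table`` holds abundances (taxa x samples), typically the top-N taxa
    at some rank. The pairwise dissimilarity under ``metric`` is computed
    first and Ward's minimum-variance criterion is applied to it.
    """
    samples = list(table.columns)
    if len(samples) < 2:
        raise ValidationError("need at least two samples to cluster")
    # Lexicographic column order makes tie-breaking deterministic.
    ordered = sorted(samples)
    d = distance_matrix(table.loc[:, ordered], metric)
    n = len(ordered)
    condensed = d.values[np.triu_indices(n, k=1)]
    linkage = sch.linkage(condensed, method="ward")
    return Dendrogram(ordered, linkage)
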