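"""Two-cluster partitions of subjects by memory functioning.

Two routes, matching how the cohorts are split before discriminant analysis:

* :func:`two_means_1d` — k-means with k = 2 on a single model coefficient
  (B3 or B4). In one dimension the optimal clusters are contiguous in sorted
  order, so the global optimum is found exactly by scanning the n - 1
  contiguous split points; no iterative seeding, fully deterministic.
* :func:`ward_trials` — Ward minimum-variance hierarchical clustering on the
  five raw trial scores entered together, tree cut at two clusters.

Clusters are always named ``lower`` / ``higher`` memory functioning, the
``higher`` cluster being the one with the larger mean of the clustered
variable(s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .errors import InputError, NoStructureError, TieError

__all__ = ["ClusterResult", "two_means_1d", "ward_trials", "label_clusters"]

LOWER, HIGHER = "lower", "higher"


@dataclass(frozen=True)
class ClusterResult:
    """A two-way partition of subjects.

    Attributes
    ----------
    labels : ndarray of str
        Per-subject assignment, ``"lower"`` or ``"higher"``, in input order.
    sizes : dict
        Subject counts per cluster.
    centers : dict
        Mean of the clustered variable(s) per cluster (scalar, or per-column
        array for trial-score clustering).
    ranges : dict or None
        (min, max) of the clustered scalar per cluster; None for the
        multivariate case. For the 1-D exact partition the two ranges never
        overlap.
    """

    labels: np.ndarray
    sizes: dict[str, int]
    centers: dict[str, object]
    ranges: dict[str, tuple[float, float]] | None = None

    def indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.labels == name)


def two_means_1d(values) -> ClusterResult:
    """Globally optimal 2-cluster partition of a scalar sample.

    Minimizes within-cluster sum of squares by exhaustive scan over the
    n - 1 split points of the sorted sample (optimal 1-D clusters are
    contiguous). Ties in cost are broken toward the more balanced partition,
    then toward the lower split index.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise InputError("need a 1-D sample of at least 2 values")
    if not np.isfinite(values).all():
        raise InputError("values must be finite")
    if np.ptp(values) == 0:
        raise NoStructureError("all values identical; no 2-cluster structure")

    order = np.argsort(values, kind="stable")
    s = values[order]
    n = len(s)
    csum = np.cumsum(s)
    csq = np.cumsum(s * s)
    total_sum, total_sq = csum[-1], csq[-1]

    best = None  # (cost, imbalance, k)
    for k in range(1, n):  # left cluster = s[:k]
        left = csq[k - 1] - csum[k - 1] ** 2 / k
        right = (total_sq - csq[k - 1]) - (total_sum - csum[k - 1]) ** 2 / (n - k)
        cost = left + right
        key = (cost, abs(n - 2 * k), k)
        # tolerance on cost so float noise cannot defeat the balance tie-break
        if best is None or cost < best[0] - 1e-10 or (
            abs(cost - best[0]) <= 1e-10 and key[1:] < (best[1], best[2])
        ):
            best = key
    k = best[2]

    labels = np.empty(n, dtype=object)
    labels[order[:k]] = LOWER
    labels[order[k:]] = HIGHER
    labels = labels.astype(str)
    lo, hi = s[:k], s[k:]
    return ClusterResult(
        labels=labels,
        sizes={LOWER: int(k), HIGHER: int(n - k)},
        centers={LOWER: float(lo.mean()), HIGHER: float(hi.mean())},
        ranges={
            LOWER: (float(lo.min()), float(lo.max())),
            HIGHER: (float(hi.min()), float(hi.max())),
        },
    )


def ward_trials(trial_matrix, standardize: bool = False) -> ClusterResult:
    """Ward's minimum-variance clustering of trial scores, cut at 2 clusters.

    Rows are subjects, columns the five trial scores entered together.
    ``standardize`` optionally z-scores each column first; default is raw
    scores since all five trials share the same unit (words recalled).
    """
    X = np.asarray(trial_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("need a 2-D matrix with at least 2 subjects")
    if not np.isfinite(X).all():
        raise InputError("trial matrix contains non-finite entries")
    work = X.copy()
    if standardize:
        sd = work.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        work = (work - work.mean(axis=0)) / sd

    Z = hierarchy.linkage(work, method="ward")
    assign = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    if len(np.unique(assign)) < 2:
        raise NoStructureError("Ward tree could not be cut into 2 clusters")
    return label_clusters(assign == 1, X.mean(axis=1), column_means_of=X)


def label_clusters(mask_a, values, column_means_of=None) -> ClusterResult:
    """Name a binary partition ``lower`` / ``higher`` by cluster means.

    ``mask_a`` marks one cluster; ``values`` is the scalar each subject was
    (or is summarized as being) clustered on. The cluster with the greater
    mean is ``higher``. Naming is invariant to input order; an exact tie of
    means raises :class:`TieError` rather than guessing.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    values = np.asarray(values, dtype=float)
    if mask_a.all() or not mask_a.any():
        raise InputError("both clusters must be non-empty")
    mean_a = values[mask_a].mean()
    mean_b = values[~mask_a].mean()
    if mean_a == mean_b:
        raise TieError("cluster means are exactly equal; cannot name lower/higher")
    low_mask = mask_a if mean_a < mean_b else ~mask_a

    labels = np.where(low_mask, LOWER, HIGHER).astype(str)
    if column_means_of is not None:
        M = np.asarray(column_means_of, dtype=float)
        centers = {
            LOWER: M[low_mask].mean(axis=0),
            HIGHER: M[~low_mask].mean(axis=0),
        }
        ranges = None
    else:
        centers = {
            LOWER: float(values[low_mask].mean()),
            HIGHER: float(values[~low_mask].mean()),
        }
        ranges = {
            LOWER: (float(values[low_mask].min()), float(values[low_mask].max())),
            HIGHER: (float(values[~low_mask].min()), float(values[~low_mask].max())),
        }
    return ClusterResult(
        labels=labels,
        sizes={LOWER: int(low_mask.sum()), HIGHER: int((~low_mask).sum())},
        centers=centers,
        ranges=ranges,
    )
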