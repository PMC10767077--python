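"""Statistical outlier removal by mean k-nearest-neighbour distance.

The first stage of the measurement pipeline: for every point, the mean
Euclidean distance to its k nearest neighbours (excluding itself) is
computed on the original cloud; points whose mean distance strictly exceeds
the threshold are dropped in a single pass (the filter is not iterated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .defaults import K_NEIGHBORS, OUTLIER_THRESHOLD
from .errors import InsufficientPointsError
from .pointcloud_io import PointCloud

__all__ = ["OutlierReport", "remove_outliers"]


@dataclass(frozen=True)
class OutlierReport:
    """Outcome of :func:`remove_outliers`.

    Attributes
    ----------
    kept : the filtered cloud (input order preserved).
    removed_indices : indices into the input cloud of removed points.
    mean_knn_distance : per-input-point mean k-NN distance, meters.
    """

    kept: PointCloud
    removed_indices: np.ndarray
    mean_knn_distance: np.ndarray

    @property
    def n_removed(self) -> int:
        return int(self.removed_indices.size)


def remove_outliers(
    cloud: PointCloud,
    k: int = K_NEIGHBORS,
    threshold: float = OUTLIER_THRESHOLD,
) -> OutlierReport:
    """Drop points whose mean distance to their k nearest neighbours exceeds
    ``threshold`` (strictly).

    If the cloud has ``n <= k`` points, ``k`` is reduced to ``n - 1``.
    Neighbour search runs once on the original cloud. Exactly k neighbours
    are used; ties at the k-th distance are broken in the backend's stable
    order (differences arise only on degenerate symmetric inputs).

    Raises
    ------
    InsufficientPointsError
        For clouds with fewer than 2 points.
    """
    n = len(cloud)
    if n < 2:
        raise InsufficientPointsError(
            f"outlier removal needs >= 2 points, got {n}"
        )
    if k < 1:
        raise ValueError("k must be a positive integer")
    k_eff = min(k, n - 1)

    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(cloud.xyz)
    dist, _ = nn.kneighbors(cloud.xyz)
    mean_d = dist[:, 1:].mean(axis=1)  # column 0 is the point itself

    removed_mask = mean_d > threshold
    removed_indices = np.flatnonzero(removed_mask)
    return OutlierReport(
        kept=cloud.take(~removed_mask),
        removed_indices=removed_indices,
        mean_knn_distance=mean_d,
    )
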