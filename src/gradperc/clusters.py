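"""Cluster labeling, spanning detection and per-configuration statistics.

Clusters are connected components of occupied sites under 4-connectivity
(nearest neighbors, open boundaries).  A cluster *spans* when it touches
both the top and bottom rows, or both the left and right columns.  Labeling
is delegated to ``scipy.ndimage.label`` with a plus-shaped structuring
element; the contract is the partition, not the algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Union

import numpy as np
from scipy import ndimage

from .dynamics import LatticeState

__all__ = ["ClusterLabeling", "ClusterStats", "label_clusters", "spans", "cluster_statistics"]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class ClusterLabeling:
    """Per-site labels (0 = empty), cluster sizes and spanning labels.

    ``sizes[k]`` is the site count of cluster ``k`` for ``k >= 1``;
    ``sizes[0]`` is 0 by convention.
    """

    labels: np.ndarray
    sizes: np.ndarray
    spanning_labels: FrozenSet[int]

    @property
    def n_clusters(self) -> int:
        return len(self.sizes) - 1

    @property
    def n_occupied(self) -> int:
        return int(self.sizes.sum())


def label_clusters(state: Union[LatticeState, np.ndarray]) -> ClusterLabeling:
    """Label 4-connected clusters of occupied sites."""
    occ = state.occupied if isinstance(state, LatticeState) else np.asarray(state, dtype=bool)
    labels, n = ndimage.label(occ, structure=_STRUCT4)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    sizes[0] = 0
    tb = np.intersect1d(labels[0, :], labels[-1, :])
    lr = np.intersect1d(labels[:, 0], labels[:, -1])
    spanning = frozenset(int(k) for k in np.union1d(tb, lr) if k != 0)
    return ClusterLabeling(labels=labels, sizes=sizes, spanning_labels=spanning)


def spans(labeling: ClusterLabeling) -> bool:
    """True iff some cluster connects top to bottom or left to right."""
    return bool(labeling.spanning_labels)


@dataclass(frozen=True)
class ClusterStats:
    """Per-configuration observables at a single occupancy snapshot."""

    smax: int  # size of the largest cluster (spanning or not)
    n_nonspanning: int  # cluster count excluding spanning clusters
    histogram: Dict[int, int]  # size -> count of non-spanning clusters


def cluster_statistics(labeling: ClusterLabeling) -> ClusterStats:
    """Largest-cluster size, non-spanning cluster count and size histogram N(s)."""
    sizes = labeling.sizes[1:]
    if sizes.size == 0:
        return ClusterStats(smax=0, n_nonspanning=0, histogram={})
    smax = int(sizes.max())
    mask = np.ones(sizes.size, dtype=bool)
    for lab in labeling.spanning_labels:
        mask[lab - 1] = False
    nonspan = sizes[mask]
    counts = np.bincount(nonspan) if nonspan.size else np.zeros(1, dtype=int)
    histogram = {int(s): int(c) for s, c in enumerate(counts) if s > 0 and c > 0}
    return ClusterStats(smax=smax, n_nonspanning=int(nonspan.size), histogram=histogram)
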