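"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's cluster/critical code
paths: flood fill is a hand-written BFS, and the linear-scan critical index
relabels the configuration from scratch after every single removal.
"""

from __future__ import annotations

from collections import deque
from typing import Optional

import numpy as np
import pytest
from scipy import ndimage

from gradperc import LatticeSpec, RemovalTrajectory


def flood_fill_labels(occupied: np.ndarray) -> np.ndarray:
    """BFS connected-component labels under 4-connectivity (0 = empty)."""
    occ = np.asarray(occupied, dtype=bool)
    h, w = occ.shape
    labels = np.zeros((h, w), dtype=int)
    next_label = 0
    for i in range(h):
        for j in range(w):
            if occ[i, j] and labels[i, j] == 0:
                next_label += 1
                queue = deque([(i, j)])
                labels[i, j] = next_label
                while queue:
                    a, b = queue.popleft()
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        x, y = a + da, b + db
                        if 0 <= x < h and 0 <= y < w and occ[x, y] and labels[x, y] == 0:
                            labels[x, y] = next_label
                            queue.append((x, y))
    return labels


def partition_sets(labels: np.ndarray) -> set:
    """Cluster partition as a set of frozensets of coordinates (label-free)."""
    out = {}
    for (i, j), lab in np.ndenumerate(labels):
        if lab:
            out.setdefault(lab, set()).add((i, j))
    return {frozenset(v) for v in out.values()}


_PLUS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def spans_oracle(occupied: np.ndarray) -> bool:
    """Spanning check written directly against scipy labels (independent path)."""
    labels, _ = ndimage.label(np.asarray(occupied, dtype=bool), structure=_PLUS)
    tb = set(labels[0, :]) & set(labels[-1, :])
    lr = set(labels[:, 0]) & set(labels[:, -1])
    return bool((tb | lr) - {0})


def linear_scan_critical_index(
    trajectory: RemovalTrajectory, initial_occupancy: Optional[np.ndarray] = None
) -> int:
    """k* by relabeling from scratch after every single removal."""
    spec = trajectory.spec
    occ = (
        np.ones((spec.L, spec.L), dtype=bool)
        if initial_occupancy is None
        else np.asarray(initial_occupancy, dtype=bool).copy()
    )
    if not spans_oracle(occ):
        raise ValueError("initial configuration does not span")
    flat = trajectory.order_flat()
    for k in range(trajectory.n_removable):
        occ.reshape(-1)[flat[k]] = False
        if not spans_oracle(occ):
            return k  # k removals were applied in the last spanning configuration
    raise RuntimeError("spanning never lost")


@pytest.fixture
def small_spec() -> LatticeSpec:
    return LatticeSpec(L=5, qp=0.5)
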