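"""Red-bond critical-point search along a removal trajectory.

Removals only cut connectivity, so spanning is monotone along a trajectory:
once lost it never returns.  The unique critical index ``k*`` is the number
of removals in the last spanning configuration — applying the first ``k*``
removals leaves a spanning cluster, applying ``k* + 1`` does not.  The
removed site at step ``k* + 1`` is the red bond; ``pc`` is the occupied
fraction with the red-bond site still present.

Two independent implementations of the same contract:

* :func:`find_critical_point` — the production two-phase search: a coarse
  phase removes sites in batches (default 1% of the lattice) with a full,
  stateless relabeling at each checkpoint, then a binary search inside the
  last batch pins ``k*`` exactly.  Critical observables (Smax, the
  non-spanning cluster count and the size histogram) are measured at the
  ``k*`` configuration.
* :func:`newman_ziff_critical_index` — a reverse union-find pass in the
  spirit of the Newman–Ziff algorithm: sites are added back in reverse
  removal order while clusters merge incrementally and border contacts are
  tracked per root; the first step at which spanning appears gives the same
  ``k*``.  Serves as a cross-validation oracle for the search above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .clusters import cluster_statistics, label_clusters, spans
from .dynamics import RemovalTrajectory
from .field import LatticeSpec, ProbabilityField

__all__ = [
    "NonBreakingTrajectoryError",
    "CriticalPointResult",
    "default_check_interval",
    "occupancy_after",
    "find_critical_point",
    "newman_ziff_critical_index",
]


class NonBreakingTrajectoryError(RuntimeError):
    """Raised when spanning survives the entire trajectory.

    Possible at qp = 0, where the zero-probability perimeter ring is never
    removed and keeps spanning on its own.
    """

    def __init__(self, excluded_count: int):
        self.excluded_count = excluded_count
        super().__init__(
            "spanning never lost within the trajectory "
            f"({excluded_count} sites with q=0 are never removed)"
        )


@dataclass(frozen=True)
class CriticalPointResult:
    """Observables at the red-bond (last spanning) configuration."""

    spec: LatticeSpec
    critical_index: int  # k*: removals applied in the last spanning configuration
    pc: float  # occupied fraction at k*
    smax_norm: float  # largest-cluster size / L^2
    n_norm: float  # non-spanning cluster count / L^2
    histogram: Dict[int, int]  # non-spanning cluster-size histogram N(s)


def default_check_interval(L: int) -> int:
    """Coarse-phase batch size: 1% of the lattice, at least one site."""
    return max(1, (L * L) // 100)


def occupancy_after(
    trajectory: RemovalTrajectory, k: int, initial_occupancy: Optional[np.ndarray] = None
) -> np.ndarray:
    """Occupancy grid after applying the first ``k`` removals of the trajectory."""
    spec = trajectory.spec
    if initial_occupancy is None:
        occ = np.ones((spec.L, spec.L), dtype=bool)
    else:
        occ = np.asarray(initial_occupancy, dtype=bool).copy()
    occ.reshape(-1)[trajectory.order_flat()[:k]] = False
    return occ


def find_critical_point(
    field: ProbabilityField,
    trajectory: RemovalTrajectory,
    check_interval: Optional[int] = None,
    initial_occupancy: Optional[np.ndarray] = None,
) -> CriticalPointResult:
    """Locate k* by coarse batched checks followed by binary search.

    Every spanning check is a fresh full relabeling of the configuration;
    the bracket invariant (spans at ``lo``, not at ``hi``) is maintained
    throughout, so the returned index satisfies spans(k*) and not
    spans(k*+1) by construction.
    """
    spec = trajectory.spec
    n = trajectory.n_removable
    step = default_check_interval(spec.L) if check_interval is None else int(check_interval)
    if step < 1:
        raise ValueError(f"check_interval must be >= 1, got {step}")

    def spanning_at(k: int) -> bool:
        return spans(label_clusters(occupancy_after(trajectory, k, initial_occupancy)))

    if not spanning_at(0):
        raise ValueError("initial configuration does not span; no critical point exists")
    if spanning_at(n):
        raise NonBreakingTrajectoryError(int(trajectory.excluded.sum()))

    lo = 0  # spans
    hi = n  # does not span
    k = step
    while k < n:
        if spanning_at(k):
            lo = k
            k += step
        else:
            hi = k
            break
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if spanning_at(mid):
            lo = mid
        else:
            hi = mid
    k_star = lo

    occ = occupancy_after(trajectory, k_star, initial_occupancy)
    labeling = label_clusters(occ)
    stats = cluster_statistics(labeling)
    n_sites = spec.n_sites
    return CriticalPointResult(
        spec=spec,
        critical_index=k_star,
        pc=float(occ.sum() / n_sites),
        smax_norm=stats.smax / n_sites,
        n_norm=stats.n_nonspanning / n_sites,
        histogram=stats.histogram,
    )


# border-contact bits per union-find root
_TOP, _BOTTOM, _LEFT, _RIGHT = 1, 2, 4, 8


def newman_ziff_critical_index(
    trajectory: RemovalTrajectory, initial_occupancy: Optional[np.ndarray] = None
) -> int:
    """k* via a single reverse union-find pass (independent oracle).

    Processes the trajectory backwards: starting from the configuration with
    every trajectory site removed, sites are re-added one by one while
    merging clusters and OR-ing border-contact bitmasks at the roots.  The
    first configuration that spans corresponds to k* removals.
    """
    spec = trajectory.spec
    L = spec.L
    n_sites = spec.n_sites
    order_flat = trajectory.order_flat()

    if initial_occupancy is None:
        base = np.ones(n_sites, dtype=bool)
    else:
        base = np.asarray(initial_occupancy, dtype=bool).reshape(-1).copy()
    base[order_flat] = False

    parent = list(range(n_sites))
    size = [1] * n_sites
    mask = [0] * n_sites
    present = [False] * n_sites
    spanning = False

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]  # path halving
            i = parent[i]
        return i

    def add(i: int) -> None:
        nonlocal spanning
        present[i] = True
        r, c = divmod(i, L)
        m = 0
        if r == 0:
            m |= _TOP
        if r == L - 1:
            m |= _BOTTOM
        if c == 0:
            m |= _LEFT
        if c == L - 1:
            m |= _RIGHT
        mask[i] = m
        for j in (i - L, i + L, i - 1, i + 1):
            if j == i - 1 and c == 0:
                continue
            if j == i + 1 and c == L - 1:
                continue
            if 0 <= j < n_sites and present[j]:
                ra, rb = find(i), find(j)
                if ra != rb:
                    if size[ra] < size[rb]:
                        ra, rb = rb, ra
                    parent[rb] = ra
                    size[ra] += size[rb]
                    mask[ra] |= mask[rb]
        root = find(i)
        mr = mask[root]
        if (mr & _TOP and mr & _BOTTOM) or (mr & _LEFT and mr & _RIGHT):
            spanning = True

    for i in np.flatnonzero(base):
        add(int(i))
    if spanning:
        raise NonBreakingTrajectoryError(int(trajectory.excluded.sum()))

    n = len(order_flat)
    for j in range(n - 1, -1, -1):
        add(int(order_flat[j]))
        if spanning:
            return j  # j removals applied in the last spanning configuration
    raise ValueError("initial configuration does not span; no critical point exists")
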