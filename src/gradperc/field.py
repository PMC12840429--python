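"""Distance-dependent removal-probability field.

The model places a damage source (a "tumor cell" in the motivating
application) at the center of an ``L x L`` square lattice.  When a site at
distance ``d`` from the center is inspected, it is removed with probability

    q(d, qp) = 1 - (1 - qp) * d / dmax,        dmax = (L - 1) / 2,

so ``q = 1`` exactly at the center and ``q = qp`` on the lattice perimeter.
``qp`` (the perimeter parameter) controls the steepness of the gradient:
``qp = 1`` recovers uniform (classical) removal, ``qp = 0`` is the maximum
gradient with a perfectly protected boundary.

Three distance metrics are supported, each giving a different shape of
iso-probability contour:

* ``chebyshev`` (L-infinity) — square contours aligned with the lattice;
* ``euclidean`` (L2) — circular contours;
* ``manhattan`` (L1) — diamond contours.

For the L2/L1 metrics the lattice corners lie farther than ``dmax`` from the
center, so the raw linear form can go below zero; values are clamped to
``[0, 1]`` to stay valid probabilities.  The normalization constant stays
``dmax`` for every metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "METRICS",
    "LatticeSpec",
    "ProbabilityField",
    "site_distance",
    "removal_probability",
    "build_field",
]

METRICS = ("chebyshev", "euclidean", "manhattan")


@dataclass(frozen=True)
class LatticeSpec:
    """Immutable simulation parameters.

    Parameters
    ----------
    L
        Lattice side (sites per row).  Must be odd and at least 3 so that a
        unique central site exists; an even ``L`` raises ``ValueError``
        rather than guessing a center convention.
    qp
        Removal probability at the lattice perimeter, in ``[0, 1]``.
    metric
        Distance metric, one of ``METRICS``.
    """

    L: int
    qp: float
    metric: str = "chebyshev"

    def __post_init__(self) -> None:
        if not isinstance(self.L, (int, np.integer)) or isinstance(self.L, bool):
            raise ValueError(f"L must be an integer, got {self.L!r}")
        if self.L < 3:
            raise ValueError(f"L must be >= 3, got {self.L}")
        if self.L % 2 == 0:
            raise ValueError(
                f"L must be odd so the lattice has a unique central site; got {self.L}"
            )
        if not 0.0 <= self.qp <= 1.0:
            raise ValueError(f"qp must lie in [0, 1], got {self.qp}")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")

    @property
    def center(self) -> Tuple[int, int]:
        """0-based (row, column) of the central site."""
        c = (self.L - 1) // 2
        return (c, c)

    @property
    def dmax(self) -> float:
        """Distance from the center to the middle of a lattice edge."""
        return (self.L - 1) / 2

    @property
    def n_sites(self) -> int:
        return self.L * self.L


def site_distance(site: Tuple[int, int], spec: LatticeSpec) -> float:
    """Distance of ``site`` (row, col) from the lattice center under ``spec.metric``."""
    x, y = site
    if not (0 <= x <= spec.L - 1 and 0 <= y <= spec.L - 1):
        raise ValueError(f"site {site!r} outside [0, {spec.L - 1}]^2")
    xc, yc = spec.center
    dx, dy = abs(x - xc), abs(y - yc)
    if spec.metric == "chebyshev":
        return float(max(dx, dy))
    if spec.metric == "euclidean":
        return float(np.hypot(dx, dy))
    return float(dx + dy)


def removal_probability(d: float, spec: LatticeSpec) -> float:
    """Linear-gradient removal probability at distance ``d``, clamped to [0, 1].

    Equals 1 at ``d = 0`` and ``qp`` at ``d = dmax``.
    """
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    raw = 1.0 - (1.0 - spec.qp) * d / spec.dmax
    return float(min(1.0, max(0.0, raw)))


@dataclass(frozen=True)
class ProbabilityField:
    """Per-site removal probabilities on the lattice.

    ``q[i, j]`` is the clamped linear-gradient value at site ``(i, j)``.
    The grid inherits the 8 symmetries of the square from the metric.
    """

    spec: LatticeSpec
    q: np.ndarray

    @property
    def q_flat(self) -> np.ndarray:
        return self.q.reshape(-1)


def build_field(spec: LatticeSpec) -> ProbabilityField:
    """Evaluate the removal-probability gradient on the whole lattice."""
    c = spec.center[0]
    off = np.abs(np.arange(spec.L) - c).astype(float)
    if spec.metric == "chebyshev":
        d = np.maximum(off[:, None], off[None, :])
    elif spec.metric == "euclidean":
        d = np.hypot(off[:, None], off[None, :])
    else:
        d = off[:, None] + off[None, :]
    q = np.clip(1.0 - (1.0 - spec.qp) * d / spec.dmax, 0.0, 1.0)
    return ProbabilityField(spec=spec, q=q)
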