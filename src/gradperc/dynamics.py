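"""Stochastic site-removal dynamics.

Starting from a fully occupied lattice, sites are inspected in uniformly
random order and removed with their local probability ``q``: draw a uniform
``R`` in [0, 1] and remove the site iff ``R < q``.  Retained sites can be
re-inspected later, so conditional on an acceptance the removed site is
distributed proportionally to ``q`` among the occupied sites.

Two samplers realize this law:

* :func:`rejection_removal_step` / :func:`rejection_removal_order` — the
  literal inspect-and-reject loop.  Exact but slow at small ``qp`` (perimeter
  sites are re-inspected many times); used as the reference in tests.
* :func:`sample_removal_order` — an exact-equivalent accelerated sampler.
  Each site ``i`` draws an independent key ``E_i / q_i`` with ``E_i`` a unit
  exponential; sorting the keys ascending realizes successive weighted
  sampling without replacement with weights ``q_i`` (the exponential-race
  construction), so a full trajectory costs one sort.  Sites with ``q = 0``
  get an infinite key and are reported as ``excluded``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field import LatticeSpec, ProbabilityField

__all__ = [
    "LatticeState",
    "RemovalTrajectory",
    "rejection_removal_step",
    "rejection_removal_order",
    "sample_removal_order",
]


@dataclass
class LatticeState:
    """Mutable occupancy grid with its occupied-site count."""

    spec: LatticeSpec
    occupied: np.ndarray
    n_occupied: int

    @classmethod
    def fully_occupied(cls, spec: LatticeSpec) -> "LatticeState":
        return cls(
            spec=spec,
            occupied=np.ones((spec.L, spec.L), dtype=bool),
            n_occupied=spec.n_sites,
        )

    @property
    def p(self) -> float:
        """Occupied fraction."""
        return self.n_occupied / self.spec.n_sites


@dataclass(frozen=True)
class RemovalTrajectory:
    """Ordered sequence of site removals for one realization.

    ``order`` is an ``(n, 2)`` array of (row, col) coordinates in removal
    order; ``excluded`` marks sites with ``q = 0`` that are never removed.
    ``order`` and ``excluded`` together cover every lattice site.
    """

    spec: LatticeSpec
    order: np.ndarray
    excluded: np.ndarray = dc_field(repr=False, default=None)

    @property
    def n_removable(self) -> int:
        return len(self.order)

    def order_flat(self) -> np.ndarray:
        """Removal order as flat (row-major) site indices."""
        return self.order[:, 0] * self.spec.L + self.order[:, 1]


def rejection_removal_step(state, field, rng):
    """One literal inspection step; returns the removed (row, col) or ``None``.

    A uniformly chosen occupied site is inspected and emptied iff a fresh
    uniform R falls below its removal probability.
    """
    if state.n_occupied < 1:
        raise ValueError("cannot inspect an empty lattice")
    flat = np.flatnonzero(state.occupied)
    i = int(flat[rng.integers(flat.size)])
    r = rng.random()
    if r < field.q_flat[i]:
        state.occupied.flat[i] = False
        state.n_occupied -= 1
        return (i // state.spec.L, i % state.spec.L)
    return None


def rejection_removal_order(field: ProbabilityField, rng) -> RemovalTrajectory:
    """Full trajectory from the literal rejection loop (reference implementation).

    Runs until every site with ``q > 0`` has been removed.  Meant for tiny
    lattices in equivalence tests; runtime is unbounded in expectation only.
    """
    spec = field.spec
    state = LatticeState.fully_occupied(spec)
    excluded = field.q == 0.0
    n_removable = int((~excluded).sum())
    order = []
    while len(order) < n_removable:
        removed = rejection_removal_step(state, field, rng)
        if removed is not None:
            order.append(removed)
    return RemovalTrajectory(
        spec=spec, order=np.array(order, dtype=np.int64).reshape(-1, 2), excluded=excluded
    )


def sample_removal_order(field: ProbabilityField, rng) -> RemovalTrajectory:
    """Draw a full removal order distributionally identical to the rejection loop.

    Exponential-race sampler: key_i = Exp(1)/q_i, order = ascending keys.
    """
    spec = field.spec
    qf = field.q_flat
    removable = np.flatnonzero(qf > 0.0)
    keys = rng.exponential(size=removable.size) / qf[removable]
    order_flat = removable[np.argsort(keys, kind="stable")]
    order = np.column_stack(divmod(order_flat, spec.L)).astype(np.int64)
    excluded = field.q == 0.0
    return RemovalTrajectory(spec=spec, order=order, excluded=excluded)
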