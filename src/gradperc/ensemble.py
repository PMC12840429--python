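"""Seeded Monte-Carlo ensembles over realizations and perimeter parameters.

A realization is: sample a removal trajectory for the field, locate its
red-bond point, record pc, Smax/L^2, n/L^2 and the non-spanning
cluster-size histogram.  An ensemble averages N independent realizations;
a sweep repeats the ensemble over a grid of qp values.

Reproducibility contract: realization ``r`` of qp index ``qi`` uses
``numpy.random.default_rng([base_seed, qi, r])`` (the qp index is dropped
for a standalone ensemble), so the full sweep is a pure function of
``(L, metric, qp_values, N, base_seed)``.  Realizations whose trajectory
never breaks spanning (possible only at qp = 0) are counted and excluded,
never re-drawn — silent retries would bias the ensemble.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .clusters import label_clusters
from .critical import (
    CriticalPointResult,
    NonBreakingTrajectoryError,
    find_critical_point,
    occupancy_after,
)
from .dynamics import sample_removal_order
from .field import LatticeSpec, ProbabilityField, build_field

__all__ = ["EnsembleResult", "SweepResult", "run_ensemble", "sweep_qp", "snapshot_realization"]


@dataclass(frozen=True)
class EnsembleResult:
    """Averaged critical observables at one (L, qp, metric) point."""

    spec: LatticeSpec
    n_requested: int
    n_realizations: int
    n_failed: int
    mean_pc: float
    se_pc: float
    mean_smax_norm: float
    se_smax_norm: float
    mean_n_norm: float
    se_n_norm: float
    histogram: Dict[int, int]
    pc_values: np.ndarray
    smax_values: np.ndarray
    n_values: np.ndarray
    k_star_values: np.ndarray

    def to_row(self) -> dict:
        return {
            "qp": self.spec.qp,
            "one_minus_qp": 1.0 - self.spec.qp,
            "L": self.spec.L,
            "metric": self.spec.metric,
            "N_realizations": self.n_realizations,
            "n_failed": self.n_failed,
            "mean_pc": self.mean_pc,
            "se_pc": self.se_pc,
            "mean_smax_norm": self.mean_smax_norm,
            "se_smax_norm": self.se_smax_norm,
            "mean_n_norm": self.mean_n_norm,
            "se_n_norm": self.se_n_norm,
        }


def _mean_se(values: np.ndarray) -> Tuple[float, float]:
    if values.size == 1:
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))


def run_ensemble(
    spec: LatticeSpec,
    N: int,
    base_seed: int,
    *,
    subkey: Sequence[int] = (),
    check_interval: Optional[int] = None,
) -> EnsembleResult:
    """Average N independent realizations at a single qp."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    field = build_field(spec)
    pcs, smaxs, ns, kstars = [], [], [], []
    histogram: Counter = Counter()
    n_failed = 0
    for r in range(N):
        rng = np.random.default_rng([int(base_seed), *map(int, subkey), r])
        trajectory = sample_removal_order(field, rng)
        try:
            res = find_critical_point(field, trajectory, check_interval=check_interval)
        except NonBreakingTrajectoryError:
            n_failed += 1
            continue
        pcs.append(res.pc)
        smaxs.append(res.smax_norm)
        ns.append(res.n_norm)
        kstars.append(res.critical_index)
        histogram.update(res.histogram)
    if not pcs:
        raise RuntimeError(
            f"all {N} realizations at qp={spec.qp} kept spanning (non-breaking trajectories)"
        )
    pcs = np.array(pcs)
    smaxs = np.array(smaxs)
    ns = np.array(ns)
    mean_pc, se_pc = _mean_se(pcs)
    mean_smax, se_smax = _mean_se(smaxs)
    mean_n, se_n = _mean_se(ns)
    return EnsembleResult(
        spec=spec,
        n_requested=N,
        n_realizations=len(pcs),
        n_failed=n_failed,
        mean_pc=mean_pc,
        se_pc=se_pc,
        mean_smax_norm=mean_smax,
        se_smax_norm=se_smax,
        mean_n_norm=mean_n,
        se_n_norm=se_n,
        histogram=dict(sorted(histogram.items())),
        pc_values=pcs,
        smax_values=smaxs,
        n_values=ns,
        k_star_values=np.array(kstars, dtype=int),
    )


@dataclass(frozen=True)
class SweepResult:
    """One ensemble per qp; summary rows sorted by (1 - qp) ascending."""

    summary: pd.DataFrame
    results: Dict[float, EnsembleResult]

    def histogram(self, qp: float) -> Dict[int, int]:
        return self.results[qp].histogram


def sweep_qp(
    L: int,
    metric: str,
    qp_values: Sequence[float],
    N: int,
    base_seed: int,
    *,
    allow_qp_zero: bool = False,
    check_interval: Optional[int] = None,
) -> SweepResult:
    """Run ensembles across a grid of perimeter parameters."""
    if len(qp_values) == 0:
        raise ValueError("qp_values must be non-empty")
    for qp in qp_values:
        if qp == 0.0 and not allow_qp_zero:
            raise ValueError(
                "qp=0 may never break spanning (the q=0 perimeter ring survives); "
                "pass allow_qp_zero=True to run it anyway"
            )
        if not 0.0 <= qp <= 1.0:
            raise ValueError(f"qp values must lie in [0, 1], got {qp}")
    results: Dict[float, EnsembleResult] = {}
    rows = []
    for qi, qp in enumerate(qp_values):
        spec = LatticeSpec(L=L, qp=float(qp), metric=metric)
        res = run_ensemble(
            spec, N, base_seed, subkey=(qi,), check_interval=check_interval
        )
        results[float(qp)] = res
        rows.append(res.to_row())
    summary = (
        pd.DataFrame(rows).sort_values("one_minus_qp", kind="stable").reset_index(drop=True)
    )
    return SweepResult(summary=summary, results=results)


def snapshot_realization(
    spec: LatticeSpec, seed: int, check_interval: Optional[int] = None
) -> Tuple[ProbabilityField, np.ndarray, np.ndarray, CriticalPointResult]:
    """One realization's red-bond snapshot.

    Returns the probability field, the occupancy grid at the red-bond
    configuration, the largest-cluster mask, and the critical-point result.
    """
    field = build_field(spec)
    rng = np.random.default_rng([int(seed)])
    trajectory = sample_removal_order(field, rng)
    result = find_critical_point(field, trajectory, check_interval=check_interval)
    occ = occupancy_after(trajectory, result.critical_index)
    labeling = label_clusters(occ)
    largest_label = int(np.argmax(labeling.sizes))
    largest = labeling.labels == largest_label
    return field, occ, largest, result
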