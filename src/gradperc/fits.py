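"""Fitted quantities derived from ensemble output.

* :func:`estimate_tau` — Fisher exponent of the critical cluster-size
  distribution N(s) ~ s^-tau, by a least-squares slope on the
  logarithmically binned (factor-2 edges) size histogram.
* :func:`fit_pc_polynomial` — fourth-order polynomial pc = sum a_i (1-qp)^i,
  weighted by inverse squared standard errors when available.
* :func:`fit_smax_line` — straight-line fit of the normalized largest
  cluster Smax/L^2 against (1-qp).

Each log bin contributes one point: its count density (count / bin width)
at the mass-weighted mean size of the bin.  The mass-weighted abscissa
makes the binned slope essentially exact on a pure power law, where the
geometric bin center systematically overestimates the exponent at small s.
The default fit window is s in [5, s90], with s90 the size below which 90%
of the non-spanning occupied mass lies after dropping the single largest
cluster: the lower cut avoids small-s lattice curvature, the upper cut the
finite-size bump near the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "InsufficientDataError",
    "PowerLawFit",
    "CurveFit",
    "default_fit_range",
    "estimate_tau",
    "fit_pc_polynomial",
    "fit_smax_line",
    "tau_by_row",
]


class InsufficientDataError(ValueError):
    """Not enough points/bins to perform the requested fit."""


@dataclass(frozen=True)
class PowerLawFit:
    tau: float
    fit_range: Tuple[float, float]
    n_bins: int
    r_squared: float


@dataclass(frozen=True)
class CurveFit:
    kind: str  # "polynomial4" | "linear"
    coefficients: Tuple[float, ...]  # a0..a4, or (intercept, slope)
    r_squared: float
    reduced_chi_square: Optional[float] = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(c * x**i for i, c in enumerate(self.coefficients))


def _hist_arrays(histogram: Mapping[int, float]) -> Tuple[np.ndarray, np.ndarray]:
    if not histogram:
        raise InsufficientDataError("empty histogram")
    s = np.array(sorted(histogram), dtype=float)
    c = np.array([histogram[int(k)] for k in s], dtype=float)
    keep = c > 0
    return s[keep], c[keep]


def default_fit_range(histogram: Mapping[int, float]) -> Tuple[float, float]:
    """[5, s90]: s90 is the 90th-percentile occupied-mass size, largest cluster dropped."""
    s, c = _hist_arrays(histogram)
    c = c.copy()
    c[-1] -= 1  # drop one instance of the largest size
    mass = s * c
    total = mass.sum()
    if total <= 0:
        raise InsufficientDataError("histogram carries no mass below its largest cluster")
    cum = np.cumsum(mass)
    s90 = float(s[np.searchsorted(cum, 0.9 * total)])
    return (5.0, max(s90, 5.0))


def estimate_tau(
    histogram: Mapping[int, float],
    fit_range: Optional[Tuple[float, float]] = None,
    min_bins: int = 4,
) -> PowerLawFit:
    """Fit N(s) ~ s^-tau on factor-2 log bins; tau is minus the log-log slope."""
    s, c = _hist_arrays(histogram)
    if fit_range is None:
        fit_range = default_fit_range(histogram)
    lo, hi = float(fit_range[0]), float(fit_range[1])

    n_bins_total = int(np.ceil(np.log2(s.max() + 1))) + 1
    edges = 2.0 ** np.arange(n_bins_total + 1)  # 1, 2, 4, ...
    xs, ys = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        if a < lo or b - 1 > hi:  # only bins fully inside the fit window
            continue
        in_bin = (s >= a) & (s < b)
        count = c[in_bin].sum()
        if count <= 0:
            continue
        x = float((s[in_bin] * c[in_bin]).sum() / count)  # mass-weighted mean size
        xs.append(x)
        ys.append(count / (b - a))
    if len(xs) < min_bins:
        raise InsufficientDataError(
            f"only {len(xs)} non-empty log bins in fit range [{lo}, {hi}]; need >= {min_bins}"
        )
    lx, ly = np.log(xs), np.log(ys)
    fit = sp_stats.linregress(lx, ly)
    return PowerLawFit(
        tau=float(-fit.slope),
        fit_range=(lo, hi),
        n_bins=len(xs),
        r_squared=float(fit.rvalue**2),
    )


def fit_pc_polynomial(table: pd.DataFrame) -> CurveFit:
    """Quartic fit of mean_pc on (1-qp); WLS with 1/se^2 weights when available."""
    x = np.asarray(table["one_minus_qp"], dtype=float)
    y = np.asarray(table["mean_pc"], dtype=float)
    if np.unique(x).size < 6:
        raise InsufficientDataError(
            f"polynomial fit needs >= 6 distinct (1-qp) points, got {np.unique(x).size}"
        )
    se = None
    if "se_pc" in table.columns:
        se_arr = np.asarray(table["se_pc"], dtype=float)
        if np.all(np.isfinite(se_arr)) and np.all(se_arr > 0):
            se = se_arr
    design = np.vander(x, 5, increasing=True)
    if se is not None:
        w = 1.0 / se
        coeffs, _, rank, _ = np.linalg.lstsq(design * w[:, None], y * w, rcond=None)
    else:
        coeffs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 5:
        raise np.linalg.LinAlgError("rank-deficient design matrix for the quartic fit")
    yhat = design @ coeffs
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    red_chi2 = None
    if se is not None and len(x) > 5:
        red_chi2 = float((((y - yhat) / se) ** 2).sum() / (len(x) - 5))
    return CurveFit(
        kind="polynomial4",
        coefficients=tuple(float(a) for a in coeffs),
        r_squared=r2,
        reduced_chi_square=red_chi2,
    )


def fit_smax_line(table: pd.DataFrame) -> CurveFit:
    """Straight line mean_smax_norm vs (1-qp); coefficients are (intercept, slope)."""
    x = np.asarray(table["one_minus_qp"], dtype=float)
    y = np.asarray(table["mean_smax_norm"], dtype=float)
    if np.unique(x).size < 3:
        raise InsufficientDataError(
            f"line fit needs >= 3 distinct (1-qp) points, got {np.unique(x).size}"
        )
    fit = sp_stats.linregress(x, y)
    return CurveFit(
        kind="linear",
        coefficients=(float(fit.intercept), float(fit.slope)),
        r_squared=float(fit.rvalue**2),
    )


def tau_by_row(
    histograms: Mapping[float, Mapping[int, float]],
    fit_range: Optional[Tuple[float, float]] = None,
) -> pd.DataFrame:
    """Fisher exponent per qp; rows with too few bins get tau = NaN.

    ``histograms`` maps qp -> aggregated critical N(s).
    """
    rows = []
    for qp, hist in histograms.items():
        try:
            fit = estimate_tau(hist, fit_range=fit_range)
            rows.append(
                {
                    "qp": qp,
                    "one_minus_qp": 1.0 - qp,
                    "tau": fit.tau,
                    "n_bins": fit.n_bins,
                    "r_squared": fit.r_squared,
                }
            )
        except InsufficientDataError:
            rows.append(
                {
                    "qp": qp,
                    "one_minus_qp": 1.0 - qp,
                    "tau": np.nan,
                    "n_bins": 0,
                    "r_squared": np.nan,
                }
            )
    return (
        pd.DataFrame(rows).sort_values("one_minus_qp", kind="stable").reset_index(drop=True)
    )
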