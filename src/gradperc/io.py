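"""Plain-text writers and readers: CSV, JSON, text matrices and ASCII PGM.

Everything is text-only (PGM images use the ASCII ``P2`` variant) so that
output interoperates with any toolchain without codecs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .critical import CriticalPointResult
from .dynamics import RemovalTrajectory
from .field import ProbabilityField

__all__ = [
    "write_field_text",
    "write_field_pgm",
    "write_occupancy_pgm",
    "write_labels_text",
    "write_trajectory_csv",
    "write_realizations_csv",
    "write_histogram_csv",
    "read_histogram_csv",
    "write_summary_csv",
    "read_summary_csv",
    "write_fit_json",
    "write_provenance",
]

PathLike = Union[str, Path]


def _write_pgm(values: np.ndarray, path: PathLike) -> None:
    """ASCII (P2) PGM, 8-bit grayscale."""
    values = np.asarray(values)
    h, w = values.shape
    lines = [f"P2", f"{w} {h}", "255"]
    for row in values:
        lines.append(" ".join(str(int(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_field_text(field: ProbabilityField, path: PathLike) -> None:
    """One lattice row per line, space-separated removal probabilities."""
    np.savetxt(path, field.q, fmt="%.6f")


def write_field_pgm(field: ProbabilityField, path: PathLike) -> None:
    """Render the field: darker pixels = higher probability of remaining (1-q).

    The light center (q = 1, certain removal) fades into a dark, protected
    perimeter; iso-probability contours appear as gray bands whose shape
    follows the distance metric.
    """
    _write_pgm(np.rint(255 * field.q), path)


def write_occupancy_pgm(occupied: np.ndarray, path: PathLike) -> None:
    """Occupied sites black (0), empty sites white (255)."""
    _write_pgm(np.where(np.asarray(occupied, dtype=bool), 0, 255), path)


def write_labels_text(labels: np.ndarray, path: PathLike) -> None:
    np.savetxt(path, labels, fmt="%d")


def write_trajectory_csv(
    trajectory: RemovalTrajectory, field: ProbabilityField, path: PathLike
) -> None:
    q_at = field.q_flat[trajectory.order_flat()]
    df = pd.DataFrame(
        {
            "step": np.arange(trajectory.n_removable),
            "row": trajectory.order[:, 0],
            "col": trajectory.order[:, 1],
            "q_at_site": q_at,
        }
    )
    df.to_csv(path, index=False)


def write_realizations_csv(
    results: Iterable[CriticalPointResult], seeds: Iterable[int], path: PathLike
) -> None:
    rows = [
        {
            "seed": seed,
            "qp": res.spec.qp,
            "L": res.spec.L,
            "metric": res.spec.metric,
            "k_star": res.critical_index,
            "pc": res.pc,
            "smax_norm": res.smax_norm,
            "n_norm": res.n_norm,
        }
        for seed, res in zip(seeds, results)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_histogram_csv(histogram: Mapping[int, int], path: PathLike) -> None:
    """Long-format cluster-size histogram: columns s, count."""
    df = pd.DataFrame(sorted(histogram.items()), columns=["s", "count"])
    df.to_csv(path, index=False)


def read_histogram_csv(path: PathLike) -> Dict[int, int]:
    df = pd.read_csv(path)
    return {int(s): int(c) for s, c in zip(df["s"], df["count"])}


def write_summary_csv(summary: pd.DataFrame, path: PathLike) -> None:
    summary.to_csv(path, index=False)


def read_summary_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_fit_json(fits: Mapping[str, object], path: PathLike) -> None:
    Path(path).write_text(json.dumps(_jsonable(fits), indent=2) + "\n")


def write_provenance(config: Mapping[str, object], path: PathLike) -> None:
    """Machine-readable record sufficient to reproduce an output directory."""
    from . import __version__

    payload = {"gradperc_version": __version__, **_jsonable(config)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
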