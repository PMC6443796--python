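"""Two-parameter (W_e, G_e) region classification of the reduced model.

Each point of the external-condition plane is classified pointwise from
its steady-state count: three roots mean bistability; a single root is
labelled induced or uninduced depending on whether the anti-termination
function at the root is above or below its half-saturation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .model_core import Environment, ReducedParams, rho_W
from .steady_state import SteadyStateSet, find_steady_states

__all__ = ["RegionLabel", "BifurcationGrid", "classify_point", "region_scan", "export_grid", "read_grid"]

GRID_HEADER = ["we_mM", "ge_mM", "label", "n_roots", "w_roots"]


class RegionLabel(str, Enum):
    UNINDUCED = "UNINDUCED"
    BISTABLE = "BISTABLE"
    INDUCED = "INDUCED"


@dataclass(frozen=True)
class BifurcationGrid:
    """Region labels over the Cartesian product of two condition grids.

    ``labels[i, j]`` corresponds to ``(we_values[i], ge_values[j])``;
    ``n_roots`` and ``w_roots`` carry the per-point steady-state detail.
    """

    we_values: tuple[float, ...]
    ge_values: tuple[float, ...]
    labels: np.ndarray  # dtype=object of RegionLabel, shape (n_we, n_ge)
    n_roots: np.ndarray  # int, same shape
    w_roots: list[list[tuple[float, ...]]]
    params: ReducedParams


def classify_point(
    env: Environment,
    params: ReducedParams,
    induced_threshold: float = 0.5,
) -> RegionLabel:
    """Label one condition: BISTABLE on 3 roots, else INDUCED when
    ``rho_W(w*) >= induced_threshold`` at the single root, else UNINDUCED."""
    ss = find_steady_states(env, params)
    return _label_from_set(ss, params, induced_threshold)


def _label_from_set(
    ss: SteadyStateSet, params: ReducedParams, induced_threshold: float = 0.5
) -> RegionLabel:
    if len(ss) == 3:
        return RegionLabel.BISTABLE
    w_star = ss.states[-1].w_star if len(ss) else 0.0
    if rho_W(w_star, params) >= induced_threshold:
        return RegionLabel.INDUCED
    return RegionLabel.UNINDUCED


def region_scan(
    we_grid: Sequence[float],
    ge_grid: Sequence[float],
    params: ReducedParams,
    induced_threshold: float = 0.5,
) -> BifurcationGrid:
    """Classify every (W_e, G_e) pair of the two grids."""
    we = tuple(float(v) for v in we_grid)
    ge = tuple(float(v) for v in ge_grid)
    if not we or not ge:
        raise ValueError("grids must be non-empty")
    if any(v < 0 for v in we + ge):
        raise ValueError("grid values must be non-negative")
    labels = np.empty((len(we), len(ge)), dtype=object)
    n_roots = np.zeros((len(we), len(ge)), dtype=int)
    w_roots: list[list[tuple[float, ...]]] = []
    for i, w_e in enumerate(we):
        row: list[tuple[float, ...]] = []
        for j, g_e in enumerate(ge):
            ss = find_steady_states(Environment(G_e=g_e, W_e=w_e), params)
            labels[i, j] = _label_from_set(ss, params, induced_threshold)
            n_roots[i, j] = len(ss)
            row.append(tuple(s.w_star for s in ss))
        w_roots.append(row)
    return BifurcationGrid(we, ge, labels, n_roots, w_roots, params)


def export_grid(grid: BifurcationGrid, path: str | Path) -> None:
    """Write the grid row-major as CSV: we_mM, ge_mM, label, n_roots, w_roots."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GRID_HEADER)
        for i, w_e in enumerate(grid.we_values):
            for j, g_e in enumerate(grid.ge_values):
                roots = ";".join(f"{w:.9g}" for w in grid.w_roots[i][j])
                writer.writerow(
                    [f"{w_e:.9g}", f"{g_e:.9g}", grid.labels[i, j].value,
                     int(grid.n_roots[i, j]), roots]
                )


def read_grid(path: str | Path) -> list[dict]:
    """Read back an exported grid CSV as a list of row dicts."""
    rows: list[dict] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                {
                    "we_mM": float(rec["we_mM"]),
                    "ge_mM": float(rec["ge_mM"]),
                    "label": RegionLabel(rec["label"]),
                    "n_roots": int(rec["n_roots"]),
                    "w_roots": tuple(
                        float(x) for x in rec["w_roots"].split(";") if x
                    ),
                }
            )
    return rows
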