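"""Ground-truth synthetic inputs: cell populations and microscopy stacks.

Three generators, all seed-deterministic:

* :func:`sample_population` draws per-cell total fluorescence from a
  two-component gamma mixture and allocates a focus share above a
  threshold (foci appear only in high-expressing cells);
* :func:`model_linked_population` maps reduced-model stable steady states
  to noisy per-cell fluorescence, producing bimodal populations exactly
  when the condition is bistable;
* :func:`render_frames` draws rod-shaped cells into bright-field and
  fluorescence frame stacks with per-frame noise, returning truth masks
  and per-cell intensity records.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import Environment, ReducedParams
from .steady_state import find_steady_states

__all__ = [
    "PopulationSpec",
    "ImageSpec",
    "CellTruth",
    "sample_population",
    "model_linked_population",
    "render_frames",
]

#: Pixel calibration: 15 px/um puts a 1.02 um rod width at ~15 px and a
#: typical rod footprint near the 190 px calibration target.
PX_PER_UM = 15.0


@dataclass(frozen=True)
class PopulationSpec:
    """Mixture truth plus the focus-allocation rule for one population."""

    n_cells: int
    omega: float
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    foci_threshold: float = np.inf  # totals above this may form a focus
    foci_fraction_range: tuple[float, float] = (0.3, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ImageSpec:
    """Geometry and noise model for synthetic microscopy stacks."""

    rows: int = 480
    cols: int = 720
    n_frames: int = 200
    rod_length_px: float = 17.0  # near-round rods keep the footprint near 190 px
    rod_width_px: float = 1.02 * PX_PER_UM
    background_mean: float = 20.0
    bright_background: float = 200.0
    bright_cell: float = 40.0
    read_noise_sd: float = 2.0
    # foci are compact near-uniform discs: a Gaussian profile would leak
    # most of its mass below the 90-grey foci/dispersed split within an
    # 8-bit range. 150 sits between the split (90) and saturation (255).
    focus_amplitude: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.n_frames < 1:
            raise ValueError("frame geometry must be positive")


@dataclass
class CellTruth:
    cell_id: int
    total_fluor: float
    dispersed_fluor: float
    foci_fluor: float


def sample_population(spec: PopulationSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a per-cell fluorescence table with its truth record.

    Totals come from the mixture; cells whose total exceeds
    ``foci_threshold`` allocate a uniform-draw fraction of it to a polar
    focus, all others are fully dispersed.  Dispersed + foci equals the
    total exactly for every row.
    """
    rng = np.random.default_rng(spec.seed)
    comp = rng.random(spec.n_cells) < spec.omega
    totals = np.where(
        comp,
        rng.gamma(spec.alpha1, spec.beta1, size=spec.n_cells),
        rng.gamma(spec.alpha2, spec.beta2, size=spec.n_cells),
    )
    lo, hi = spec.foci_fraction_range
    focus_frac = np.where(
        totals > spec.foci_threshold, rng.uniform(lo, hi, size=spec.n_cells), 0.0
    )
    foci = totals * focus_frac
    dispersed = totals - foci
    totals = dispersed + foci  # re-sum so additivity is exact in floats
    table = pd.DataFrame(
        {
            "cell_id": np.arange(spec.n_cells),
            "total_fluor": totals,
            "dispersed_fluor": dispersed,
            "foci_fluor": foci,
            "component": np.where(comp, 1, 2),
        }
    )
    truth = {
        "generator": "sample_population",
        "spec": {
            **{k: (v if np.isfinite(v) else "inf") if isinstance(v, float) else v
               for k, v in asdict(spec).items()},
        },
    }
    return table, truth


def model_linked_population(
    env: Environment,
    params: ReducedParams,
    noise_cv: float = 0.3,
    n_cells: int = 1000,
    seed: int = 0,
    fluor_scale: float = 150.0,
    basal: float = 5.0,
    basin_weights: tuple[float, ...] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell fluorescence linked to the model's stable steady states.

    Each cell is assigned to one stable steady state (default equal basin
    weights) and observes ``basal + fluor_scale * p*`` multiplied by
    lognormal noise of coefficient of variation ``noise_cv``.  Bistable
    conditions therefore produce two clusters, monostable ones a single
    cluster.  This observable map is an explicit stand-in: the model is
    deterministic and does not itself predict population partitioning.
    """
    ss = find_steady_states(env, params)
    stable = ss.stable_states
    if not stable:
        raise RuntimeError("no stable steady state found")
    if basin_weights is None:
        basin_weights = tuple(1.0 / len(stable) for _ in stable)
    if len(basin_weights) != len(stable):
        raise ValueError("one basin weight per stable state required")
    weights = np.asarray(basin_weights, dtype=float)
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    idx = rng.choice(len(stable), size=n_cells, p=weights)
    means = np.array([basal + fluor_scale * s.p_star for s in stable])[idx]
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_cells)
    else:
        noise = np.ones(n_cells)
    totals = means * noise
    table = pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "total_fluor": totals,
            "dispersed_fluor": totals,
            "foci_fluor": np.zeros(n_cells),
            "steady_state_index": idx,
        }
    )
    truth = {
        "generator": "model_linked_population",
        "env": {"G_e": env.G_e, "W_e": env.W_e},
        "n_stable_states": len(stable),
        "p_star": [s.p_star for s in stable],
        "basin_weights": list(weights),
        "noise_cv": noise_cv,
        "fluor_scale": fluor_scale,
        "basal": basal,
        "seed": seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------

def _rod_mask(shape, center, length, width, angle) -> np.ndarray:
    """Boolean mask of a capsule (rectangle with semicircular caps)."""
    rows, cols = shape
    half = max(length / 2.0 - width / 2.0, 0.0)
    c, s = np.cos(angle), np.sin(angle)
    # bounding box
    r0 = max(int(center[0] - length), 0)
    r1 = min(int(center[0] + length) + 1, rows)
    c0 = max(int(center[1] - length), 0)
    c1 = min(int(center[1] + length) + 1, cols)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - center[0]
    dx = cc - center[1]
    u = dx * c + dy * s  # along axis
    v = -dx * s + dy * c
    uc = np.clip(u, -half, half)
    dist2 = (u - uc) ** 2 + v**2
    local = dist2 <= (width / 2.0) ** 2
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = local
    return mask


def _pole_coords(center, length, width, angle, rng):
    half = max(length / 2.0 - width / 2.0, 0.0)
    sign = rng.choice([-1.0, 1.0])
    return (
        center[0] + sign * half * np.sin(angle),
        center[1] + sign * half * np.cos(angle),
    )


def render_frames(
    cells: pd.DataFrame,
    spec: ImageSpec,
    max_placement_tries: int = 200,
):
    """Render a cell table into bright-field + fluorescence frame stacks.

    ``cells`` needs columns ``cell_id``, ``dispersed_fluor`` and
    ``foci_fluor`` (sums over the cell footprint, in intensity units).
    Returns ``(bright_stack, fluor_stack, truth)`` where the stacks are
    uint8 arrays of shape ``(n_frames, rows, cols)`` and ``truth`` holds
    the label mask plus per-cell placement and intensity records.
    Placement is rejection-sampled without overlap; an overcrowded spec
    raises after ``max_placement_tries`` tries per cell.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.rows, spec.cols)
    label_mask = np.zeros(shape, dtype=np.int32)
    dispersed_img = np.zeros(shape, dtype=float)
    focus_img = np.zeros(shape, dtype=float)
    occupied = np.zeros(shape, dtype=bool)
    records = []

    margin = spec.rod_length_px
    for row in cells.itertuples(index=False):
        placed = False
        for _ in range(max_placement_tries):
            center = (
                rng.uniform(margin, spec.rows - margin),
                rng.uniform(margin, spec.cols - margin),
            )
            angle = rng.uniform(0, np.pi)
            length = spec.rod_length_px * rng.uniform(0.8, 1.2)
            mask = _rod_mask(shape, center, length, spec.rod_width_px, angle)
            # enforce a 2-px separation so components never merge
            grown = np.zeros(shape, dtype=bool)
            rr, cc = np.nonzero(mask)
            for dr in (-2, 0, 2):
                for dc in (-2, 0, 2):
                    grown[np.clip(rr + dr, 0, spec.rows - 1), np.clip(cc + dc, 0, spec.cols - 1)] = True
            if not (grown & occupied).any():
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {row.cell_id}: frame overcrowded"
            )
        occupied |= grown
        area = int(mask.sum())
        label_mask[mask] = int(row.cell_id) + 1
        dispersed_total = float(row.dispersed_fluor)
        foci_total = float(row.foci_fluor)
        dispersed_img[mask] += dispersed_total / area
        focus_center = None
        if foci_total > 0:
            focus_center = _pole_coords(center, length, spec.rod_width_px, angle, rng)
            rr, cc = np.nonzero(mask)
            d2 = (rr - focus_center[0]) ** 2 + (cc - focus_center[1]) ** 2
            order = np.argsort(d2)
            amp = spec.focus_amplitude
            n_full = int(foci_total // amp)
            if n_full >= order.size:  # focus fills the cell; spread evenly
                focus_img[rr, cc] += foci_total / order.size
            else:
                sel = order[:n_full]
                focus_img[rr[sel], cc[sel]] += amp
                rem = foci_total - n_full * amp
                if rem > 0:
                    k = order[n_full]
                    focus_img[rr[k], cc[k]] += rem
        records.append(
            {
                "cell_id": int(row.cell_id),
                "center": [float(center[0]), float(center[1])],
                "angle": float(angle),
                "length_px": float(length),
                "width_px": float(spec.rod_width_px),
                "area_px": area,
                "dispersed_fluor": dispersed_total,
                "foci_fluor": foci_total,
                "total_fluor": dispersed_total + foci_total,
                "focus_center": [float(v) for v in focus_center] if focus_center else None,
            }
        )

    cell_mask = label_mask > 0
    bright_clean = np.where(cell_mask, spec.bright_cell, spec.bright_background)
    fluor_clean = spec.background_mean + dispersed_img + focus_img

    bright_stack = np.empty((spec.n_frames,) + shape, dtype=np.uint8)
    fluor_stack = np.empty((spec.n_frames,) + shape, dtype=np.uint8)
    for f in range(spec.n_frames):
        b = rng.poisson(bright_clean).astype(float)
        b += rng.normal(0.0, spec.read_noise_sd, size=shape)
        bright_stack[f] = np.clip(np.rint(b), 0, 255).astype(np.uint8)
        fl = rng.poisson(np.clip(fluor_clean, 0, None)).astype(float)
        fl += rng.normal(0.0, spec.read_noise_sd, size=shape)
        fluor_stack[f] = np.clip(np.rint(fl), 0, 255).astype(np.uint8)

    truth = {
        "generator": "render_frames",
        "spec": asdict(spec),
        "cells": records,
        "label_mask": label_mask,
        "background_mean": spec.background_mean,
    }
    return bright_stack, fluor_stack, truth


def write_truth_json(truth: dict, path: str | Path) -> None:
    """Serialize a truth record, converting arrays to lists."""
    clean = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in truth.items()
    }
    Path(path).write_text(json.dumps(clean, indent=2) + "\n")
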