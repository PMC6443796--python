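"""Single-cell fluorescence quantification from microscopy frame stacks.

Pipeline: average frames -> mask cell bodies from the bright-field image
(half-intensity threshold when contrast allows, otherwise local-adaptive
binarization of bright+fluorescence) -> keep connected components within
the area window [114, 7600] px -> subtract the mean background measured
outside all retained cells -> split each cell's corrected intensity at 90
grey levels into dispersed (< 90) and foci (>= 90) sums -> per-cell
density, dispersed fraction and width.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import filters, measure

__all__ = [
    "FrameStack",
    "CellMeasurement",
    "QuantConfig",
    "average_frames",
    "make_mask",
    "filter_components",
    "subtract_background",
    "split_fluorescence",
    "measure_cells",
    "write_cells_csv",
    "read_stack",
]

AREA_MIN = 114
AREA_MAX = 7600
FOCI_THRESHOLD = 90.0
SATURATION = 255.0

CELLS_CSV_HEADER = [
    "cell_id", "area_px", "total_fluor", "dispersed_fluor", "foci_fluor",
    "density", "dispersed_fraction", "width_px",
]


class FormatError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class FrameStack:
    """A stack of same-shape 8-bit grayscale frames."""

    frames: np.ndarray  # (n, rows, cols), uint8 or float in [0, 255]
    channel: str = "FLUOR"  # or BRIGHTFIELD

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise FormatError("frames must be a non-empty (n, rows, cols) array")
        if arr.min() < 0 or arr.max() > 255:
            raise FormatError("intensities must lie in [0, 255]")

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class CellMeasurement:
    cell_id: int
    area_px: int
    total_fluor: float
    dispersed_fluor: float
    foci_fluor: float
    density: float
    dispersed_fraction: float | None
    width_px: float
    oversaturated: bool = False


@dataclass(frozen=True)
class QuantConfig:
    """Tunable pipeline knobs; defaults mirror the reference analysis."""

    n_frames: int | None = None  # None = all frames
    sensitivity: float = 0.35
    contrast_cutoff: float = 0.3
    area_min: int = AREA_MIN
    area_max: int = AREA_MAX
    foci_threshold: float = FOCI_THRESHOLD
    adaptive_block_size: int = 51


def average_frames(stack: FrameStack, n: int | None = None) -> np.ndarray:
    """Pixelwise mean of the first ``n`` frames (all frames when None)."""
    arr = np.asarray(stack.frames, dtype=float)
    if n is None:
        n = arr.shape[0]
    if n < 1 or n > arr.shape[0]:
        raise FormatError(f"cannot average {n} of {arr.shape[0]} frames")
    return arr[:n].mean(axis=0)


def _contrast(image: np.ndarray) -> float:
    p1, p99 = np.percentile(image, [1, 99])
    return float((p99 - p1) / 255.0)


def make_mask(
    bright: np.ndarray,
    fluor: np.ndarray,
    sensitivity: float = 0.35,
    contrast_cutoff: float = 0.3,
    adaptive_block_size: int = 51,
) -> np.ndarray:
    """Binary cell-body mask from a bright-field (+ fluorescence) image.

    High-contrast bright-field images are thresholded at half their
    intensity range (cells are dark on a light background, so pixels below
    the midpoint are kept).  Low-contrast images are first summed with the
    fluorescence channel, then binarized with a local mean threshold whose
    offset is controlled by ``sensitivity`` (higher sensitivity keeps
    more foreground, mirroring adaptive binarization conventions).
    """
    bright = np.asarray(bright, dtype=float)
    fluor = np.asarray(fluor, dtype=float)
    if bright.shape != fluor.shape:
        raise FormatError("bright and fluorescence images must share a shape")
    if np.ptp(bright) == 0 and np.ptp(fluor) == 0:
        raise DegenerateInputError("all-constant input images")

    if _contrast(bright) >= contrast_cutoff:
        midpoint = 0.5 * (bright.max() + bright.min())
        return bright < midpoint

    combined = bright + fluor
    if _contrast(np.clip(combined, 0, 255)) < 0.05:
        # no resolvable structure in either channel: nothing to segment
        return np.zeros(bright.shape, dtype=bool)
    block = adaptive_block_size if adaptive_block_size % 2 == 1 else adaptive_block_size + 1
    local = filters.threshold_local(combined, block_size=block, method="mean")
    # offset scaled by sensitivity: at 0.5 the raw local mean is used
    offset = (0.5 - sensitivity) * np.std(combined)
    # cells are the locally bright structures of the combined image
    return combined > local + offset


def filter_components(
    mask: np.ndarray,
    area_min: int = AREA_MIN,
    area_max: int = AREA_MAX,
) -> np.ndarray:
    """Label 8-connected components and drop those outside [area_min, area_max].

    Bounds are inclusive.  Returns an int label image; labels are renumbered
    consecutively from 1 in scan order.
    """
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    if labels.max() == 0:
        return labels
    out = np.zeros_like(labels)
    next_id = 1
    for region in measure.regionprops(labels):
        if area_min <= region.area <= area_max:
            out[labels == region.label] = next_id
            next_id += 1
    return out


def subtract_background(fluor: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Subtract the mean intensity outside all retained cells; clip at 0.

    Returns the corrected image and the background estimate.
    """
    fluor = np.asarray(fluor, dtype=float)
    outside = labels == 0
    if not outside.any():
        raise DegenerateInputError("mask covers the whole image; no background")
    background = float(fluor[outside].mean())
    return np.clip(fluor - background, 0.0, None), background


def split_fluorescence(
    corrected: np.ndarray,
    component_mask: np.ndarray,
    foci_threshold: float = FOCI_THRESHOLD,
) -> tuple[float, float]:
    """Split one cell's corrected intensity into (dispersed, foci) sums.

    Pixels below the threshold accumulate into the dispersed sum, pixels
    at or above it into the foci sum (the boundary value counts as foci).
    """
    vals = np.asarray(corrected, dtype=float)[np.asarray(component_mask, dtype=bool)]
    dispersed = float(vals[vals < foci_threshold].sum())
    foci = float(vals[vals >= foci_threshold].sum())
    return dispersed, foci


def measure_cells(
    bright_stack: FrameStack,
    fluor_stack: FrameStack,
    config: QuantConfig = QuantConfig(),
) -> tuple[list[CellMeasurement], dict]:
    """Run the full quantification pipeline on a pair of aligned stacks.

    Returns the per-cell measurements plus a QC dict with the background
    estimate and the mean cell width per frame of the bright-field stack
    (focus stability check).
    """
    if bright_stack.frames.shape[1:] != fluor_stack.frames.shape[1:]:
        raise FormatError("bright and fluorescence stacks must be aligned")
    bright = average_frames(bright_stack, config.n_frames)
    fluor = average_frames(fluor_stack, config.n_frames)
    mask = make_mask(
        bright, fluor,
        sensitivity=config.sensitivity,
        contrast_cutoff=config.contrast_cutoff,
        adaptive_block_size=config.adaptive_block_size,
    )
    labels = filter_components(mask, config.area_min, config.area_max)
    if labels.max() == 0:
        return [], {"background": None, "mean_width_per_frame": []}
    corrected, background = subtract_background(fluor, labels)

    cells: list[CellMeasurement] = []
    for region in measure.regionprops(labels):
        comp = labels == region.label
        dispersed, foci = split_fluorescence(corrected, comp, config.foci_threshold)
        total = dispersed + foci
        area = int(region.area)
        focus_vals = corrected[comp]
        focus_vals = focus_vals[focus_vals >= config.foci_threshold]
        oversaturated = bool(focus_vals.size and focus_vals.mean() >= SATURATION)
        cells.append(
            CellMeasurement(
                cell_id=int(region.label),
                area_px=area,
                total_fluor=total,
                dispersed_fluor=dispersed,
                foci_fluor=foci,
                density=total / area,
                dispersed_fraction=(dispersed / total) if total > 0 else None,
                width_px=float(region.axis_minor_length),
                oversaturated=oversaturated,
            )
        )

    widths = _mean_width_per_frame(bright_stack, config)
    qc = {"background": background, "mean_width_per_frame": widths}
    return cells, qc


def _mean_width_per_frame(bright_stack: FrameStack, config: QuantConfig) -> list[float]:
    """Mean minor-axis width of retained components in each single frame."""
    widths: list[float] = []
    for frame in np.asarray(bright_stack.frames, dtype=float):
        midpoint = 0.5 * (frame.max() + frame.min())
        if np.ptp(frame) == 0:
            widths.append(float("nan"))
            continue
        labels = filter_components(frame < midpoint, config.area_min, config.area_max)
        regions = measure.regionprops(labels)
        if not regions:
            widths.append(float("nan"))
        else:
            widths.append(float(np.mean([r.axis_minor_length for r in regions])))
    return widths


def write_cells_csv(cells: Sequence[CellMeasurement], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CELLS_CSV_HEADER)
        for c in cells:
            writer.writerow(
                [
                    c.cell_id, c.area_px,
                    f"{c.total_fluor:.6f}", f"{c.dispersed_fluor:.6f}",
                    f"{c.foci_fluor:.6f}", f"{c.density:.6f}",
                    "" if c.dispersed_fraction is None else f"{c.dispersed_fraction:.6f}",
                    f"{c.width_px:.6f}",
                ]
            )


def read_stack(path: str | Path, channel: str = "FLUOR") -> FrameStack:
    """Read a multi-page TIFF, a single image, or a directory of numbered
    PNG/TIFF frames into a FrameStack."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise FormatError(f"no frames found in {path}")
        frames = np.stack([iio.imread(p) for p in files])
    else:
        import tifffile

        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    return FrameStack(frames=frames, channel=channel)
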